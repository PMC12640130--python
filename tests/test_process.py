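"""Forward process-model equations and uncertainty propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import omsm
from omsm.core import TracerSpec
from omsm.process import (
    FoodWebState,
    apply_discrimination,
    consumer_sd,
    food_web_length,
    forward_model,
    metazoan_steps,
    mix_base,
    trophic_uncertainty,
)

ALA = TracerSpec("Ala", discrimination_class="constant",
                 delta_meta=6.3, sigma_delta_meta=2.6)
PRO = TracerSpec("Pro", discrimination_class="constant",
                 delta_meta=5.8, sigma_delta_meta=1.7)
GLX = TracerSpec("Glx", discrimination_class="variable",
                 delta_meta=8.0, sigma_delta_meta=1.7,
                 delta_proto=0.5, sigma_delta_proto=1.0)
PHE_CONS = TracerSpec("Phe", discrimination_class="conservative")


class TestMixBase:
    def test_simplex_vertex_returns_that_source(self):
        assert mix_base([1, 0, 0], np.array([4.2, 9.9, 13.1])) == pytest.approx(4.2)

    def test_midpoint(self):
        assert mix_base([0.5, 0.5], np.array([2.0, 4.0])) == pytest.approx(3.0)

    def test_weighted_combination(self):
        assert mix_base([0.25, 0.25, 0.5], np.array([0.0, 4.0, 10.0])) == \
            pytest.approx(6.0)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            mix_base([0.7, 0.7], np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="simplex"):
            mix_base([1.2, -0.2], np.array([1.0, 2.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
           st.integers(0, 10**6))
    def test_mixture_lies_within_source_range(self, weights, seed):
        f = np.asarray(weights) / np.sum(weights)
        means = np.random.default_rng(seed).uniform(-30, 30, f.size)
        out = mix_base(f, means)
        assert means.min() - 1e-9 <= out <= means.max() + 1e-9


class TestTrophicEstimators:
    def test_no_enrichment_gives_zero_steps(self):
        assert food_web_length(5.0, 5.0, ALA) == 0.0
        assert metazoan_steps(5.0, 5.0, GLX) == 0.0

    def test_ala_two_steps(self):
        assert food_web_length(12.6, 0.0, ALA) == pytest.approx(2.0)

    def test_pro_one_step(self):
        assert food_web_length(5.8, 0.0, PRO) == pytest.approx(1.0)

    def test_glx_steps(self):
        assert metazoan_steps(16.0, 0.0, GLX) == pytest.approx(2.0)
        assert metazoan_steps(4.0, 0.0, GLX) == pytest.approx(0.5)

    def test_zero_discrimination_factor_errors(self):
        with pytest.raises(ZeroDivisionError):
            food_web_length(1.0, 0.0, PHE_CONS)


class TestTrophicUncertainty:
    def test_zero_sds_give_zero(self):
        assert trophic_uncertainty(2.0, 20.0, 0.0, 6.3, 0.0) == 0.0

    def test_hand_evaluated_quadrature(self):
        expected = 2.0 * np.sqrt((0.5 / 20.0) ** 2 + (2.6 / 6.3) ** 2)
        assert trophic_uncertainty(2.0, 20.0, 0.5, 6.3, 2.6) == \
            pytest.approx(expected, rel=1e-12)

    def test_proportional_in_mu(self):
        one = trophic_uncertainty(1.0, 20.0, 0.5, 6.3, 2.6)
        two = trophic_uncertainty(2.0, 20.0, 0.5, 6.3, 2.6)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_near_zero_consumer_delta_warns(self):
        with pytest.warns(match="delta_consumer"):
            trophic_uncertainty(1.0, 0.5, 0.2, 6.3, 1.0)


class TestDiscrimination:
    STATE = FoodWebState(f=np.array([1.0]), FWL=2.0, MTS=1.0)

    def test_conservative_identity(self):
        assert apply_discrimination(5.0, self.STATE, PHE_CONS) == 5.0

    def test_constant_pro_two_steps(self):
        assert apply_discrimination(5.0, self.STATE, PRO) == \
            pytest.approx(5.0 + 2 * 5.8)

    def test_variable_glx_one_proto_one_meta(self):
        state = FoodWebState(f=np.array([1.0]), FWL=2.0, MTS=1.0)
        assert state.PTS == pytest.approx(1.0)
        assert apply_discrimination(0.0, state, GLX) == pytest.approx(8.5)

    def test_reduction_chain(self):
        """Variable with equal proto/meta deltas reduces exactly to constant;
        constant with zero delta reduces to conservative."""
        state = FoodWebState(f=np.array([1.0]), FWL=1.7, MTS=0.9)
        equal = TracerSpec("Glx", discrimination_class="variable",
                           delta_meta=4.4, sigma_delta_meta=1.0,
                           delta_proto=4.4, sigma_delta_proto=1.0)
        const = TracerSpec("Glx", discrimination_class="constant",
                           delta_meta=4.4, sigma_delta_meta=1.0)
        assert abs(apply_discrimination(2.0, state, equal)
                   - apply_discrimination(2.0, state, const)) < 1e-12
        zero = TracerSpec("Glx", discrimination_class="constant",
                          delta_meta=0.0, sigma_delta_meta=0.0)
        assert abs(apply_discrimination(2.0, state, zero) - 2.0) < 1e-12


class TestConsumerSD:
    STATE = FoodWebState(f=np.array([1.0]), FWL=2.0, MTS=1.0)

    def test_conservative_keeps_alpha(self):
        assert consumer_sd(0.4, self.STATE, PHE_CONS) == 0.4

    def test_variable_hand_value(self):
        state = FoodWebState(f=np.array([1.0]), FWL=2.0, MTS=1.0)  # PTS = 1
        glx = TracerSpec("Glx", discrimination_class="variable",
                         delta_meta=8.0, sigma_delta_meta=1.7,
                         delta_proto=0.5, sigma_delta_proto=1.0)
        assert consumer_sd(0.5, state, glx) == \
            pytest.approx(np.sqrt(0.25 + 1.0 + 2.89), rel=1e-12)

    @pytest.mark.parametrize("fwl2, mts2", [(3.0, 1.0), (2.0, 1.5), (2.5, 1.2)])
    def test_monotone_in_trophic_steps(self, fwl2, mts2):
        base = consumer_sd(0.5, self.STATE, GLX)
        bigger = consumer_sd(0.5, FoodWebState(f=np.array([1.0]),
                                               FWL=fwl2, MTS=mts2), GLX)
        assert bigger >= base

    def test_equal_sds_do_not_collapse_variable_to_constant(self):
        """With sigma(proto) = sigma(meta) and PTS + MTS = FWL the variable
        quadrature is strictly smaller than the constant one (PTS^2 + MTS^2 <
        FWL^2 when both are positive) — the two forms must not be merged."""
        s = 1.7
        state = FoodWebState(f=np.array([1.0]), FWL=2.0, MTS=1.0)  # PTS = 1
        var = TracerSpec("Glx", discrimination_class="variable",
                         delta_meta=8.0, sigma_delta_meta=s,
                         delta_proto=0.5, sigma_delta_proto=s)
        const = TracerSpec("Glx", discrimination_class="constant",
                           delta_meta=8.0, sigma_delta_meta=s)
        sd_var = consumer_sd(0.5, state, var)
        sd_const = consumer_sd(0.5, state, const)
        assert sd_var == pytest.approx(np.sqrt(0.25 + s**2 + s**2))
        assert sd_const == pytest.approx(np.sqrt(0.25 + (2 * s) ** 2))
        assert sd_var < sd_const


class TestForwardModel:
    def tdf_map(self, tdf):
        names = ["Phe", "Lys", "Thr", "Pro", "Glx"]
        from omsm.core import default_model_config, effective_specs
        return {j: effective_specs(default_model_config(), tdf)[j]
                for j in names}

    def test_zero_trophic_steps_equals_mixing_only(self, tdf):
        tmap = self.tdf_map(tdf)
        means = np.array([[0.0, 1.0, -8.0, 3.0, 4.0],
                          [4.0, 5.0, -16.0, 8.0, 9.0]])
        f = [0.3, 0.7]
        pred = forward_model(f, 0.0, 0.0, means, tmap)
        base = mix_base(f, means)
        for idx, j in enumerate(tmap):
            assert pred[j] == pytest.approx(base[idx], abs=1e-12)

    def test_single_source_is_mean_plus_offsets(self, tdf):
        tmap = self.tdf_map(tdf)
        means = np.array([[0.0, 1.0, -8.0, 3.0, 4.0]])
        pred = forward_model([1.0], 0.5, 1.0, means, tmap)
        state = FoodWebState(f=np.array([1.0]), FWL=1.5, MTS=1.0)
        for idx, j in enumerate(tmap):
            assert pred[j] == pytest.approx(
                apply_discrimination(means[0, idx], state, tmap[j]), abs=1e-12
            )

    def test_composition_with_components(self, tdf):
        tmap = self.tdf_map(tdf)
        rng = np.random.default_rng(1)
        means = rng.normal(0, 5, (3, 5))
        f = np.array([0.2, 0.5, 0.3])
        pts, mts = 0.7, 1.4
        pred = forward_model(f, pts, mts, means, tmap)
        base = mix_base(f, means)
        state = FoodWebState(f=f, FWL=pts + mts, MTS=mts)
        for idx, j in enumerate(tmap):
            assert pred[j] == pytest.approx(
                apply_discrimination(base[idx], state, tmap[j]), abs=1e-12
            )

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.0, 1.0), st.integers(0, 10**6))
    def test_affine_in_f(self, tdf, lam, seed):
        tmap = self.tdf_map(tdf)
        rng = np.random.default_rng(seed)
        means = rng.normal(0, 5, (3, 5))
        a = rng.dirichlet(np.ones(3))
        b = rng.dirichlet(np.ones(3))
        mix = lam * a + (1 - lam) * b
        pts, mts = 0.5, 1.5
        pa = forward_model(a, pts, mts, means, tmap)
        pb = forward_model(b, pts, mts, means, tmap)
        pm = forward_model(mix, pts, mts, means, tmap)
        for j in tmap:
            assert pm[j] == pytest.approx(lam * pa[j] + (1 - lam) * pb[j],
                                          abs=1e-9)


def test_pts_is_derived_from_fwl_and_mts():
    state = FoodWebState(f=np.array([0.5, 0.5]), FWL=2.3, MTS=1.1)
    assert state.PTS == 2.3 - 1.1
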