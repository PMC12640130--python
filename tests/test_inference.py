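"""Model graph construction, log-posterior, and MCMC sampler behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omsm
from omsm.core import ModelConfig, OMSMWarning, SourceDataset, default_model_config
from omsm.inference import MCMCConfig, PriorConfig, _alr_inverse, build_model, run_mcmc

QUICK = MCMCConfig(chains=2, adapt=300, burn_in=300, samples=600, thin=6, seed=17)


@pytest.fixture(scope="module")
def small_fit(source_panel, tdf):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        consumers, truth = omsm.simulate_consumers(source_panel, n=3,
                                                   tdf=tdf, seed=21)
        model = build_model(source_panel, consumers, tdf)
        draws = run_mcmc(model, QUICK)
    return model, draws, truth


class TestBuildModel:
    def test_structure_counts(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=1, tdf=tdf,
                                               seed=1)
        model = build_model(source_panel, consumers, tdf)
        d = model.describe()
        assert d["n_simplex_dim"] == 3
        assert d["n_trophic_latents_per_consumer"] == 2
        assert d["n_mixing_likelihood_terms"] == 3  # Phe, Lys, Thr x 1 consumer
        assert d["fwl_tracer"] == "Pro" and d["mts_tracer"] == "Glx"

    def test_nonfractionating_variant_graph(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=1, tdf=tdf,
                                               seed=1)
        config = default_model_config(nonfractionating_variant=True)
        model = build_model(source_panel, consumers, tdf, config=config)
        assert "Thr" not in model.tracers
        for aa in ("Phe", "Lys"):
            spec = model.specs[aa]
            assert spec.discrimination_class == "conservative"
            assert spec.delta_meta == 0 and spec.sigma_delta_meta == 0

    def test_two_consumers_share_source_parameters(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=2, tdf=tdf,
                                               seed=2)
        model = build_model(source_panel, consumers, tdf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = run_mcmc(model, QUICK)
        names = draws.parameters
        # independent mixing vectors per consumer, one shared source block
        assert "f[sim001,surface]" in names and "f[sim002,surface]" in names
        assert sum(1 for n in names if n.startswith("mu[Phe,")) == 3

    def test_invalid_config_raises(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=1, tdf=tdf,
                                               seed=3)
        bad = ModelConfig(roles={"Phe": "mixing", "Pro": "trophic_fwl"})
        with pytest.raises(ValueError, match="invalid"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_model(source_panel, consumers, tdf, config=bad)


class TestLogPosterior:
    def point(self, model, rng):
        st = model.initial_state(rng)
        return {
            "mu": st["mu"], "sigma": st["sigma"], "f": _alr_inverse(st["z"]),
            "FWL": st["FWL"], "MTS": st["MTS"],
        }

    def test_finite_at_initialisation(self, small_fit):
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        assert np.isfinite(model.log_posterior(pt))

    def test_negative_fraction_gives_minus_inf(self, small_fit):
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        pt["f"] = pt["f"].copy()
        pt["f"][0] = [1.2, -0.2, 0.0]
        assert model.log_posterior(pt) == -np.inf

    def test_nonpositive_sigma_gives_minus_inf(self, small_fit):
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        pt["sigma"] = pt["sigma"].copy()
        pt["sigma"][0, 0] = 0.0
        assert model.log_posterior(pt) == -np.inf

    def test_mu_outside_uniform_bounds_gives_minus_inf(self, small_fit):
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        pt["mu"] = pt["mu"].copy()
        pt["mu"][0, 0] = 250.0  # beyond the ±100 ‰ prior
        assert model.log_posterior(pt) == -np.inf

    def test_doubling_sigma_changes_density_analytically(self, small_fit):
        """Scaling all source SDs changes the log-density by the closed-form
        normal-likelihood difference plus the dispersion-prior difference."""
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        pt2 = dict(pt)
        pt2["sigma"] = 2.0 * pt["sigma"]
        got = model.log_posterior(pt2) - model.log_posterior(pt)

        expected = 0.0
        for c_i, g in enumerate(model.groups):
            n = model.n_rep[c_i]
            for r in range(model.n_tracers):
                ss = (model.sum_x2[r, c_i]
                      - 2 * pt["mu"][r, c_i] * model.sum_x[r, c_i]
                      + n * pt["mu"][r, c_i] ** 2)
                s1, s2 = pt["sigma"][r, c_i], 2 * pt["sigma"][r, c_i]
                expected += (-n * np.log(s2) - ss / (2 * s2**2)) - \
                            (-n * np.log(s1) - ss / (2 * s1**2))
                expected += float(
                    model._sigma_logprior(np.array([s2]))[0]
                    - model._sigma_logprior(np.array([s1]))[0]
                )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_module_level_wrapper(self, small_fit):
        model, _, _ = small_fit
        pt = self.point(model, np.random.default_rng(0))
        assert omsm.log_posterior(pt, model) == model.log_posterior(pt)


class TestSampler:
    def test_retained_draw_counts(self, small_fit):
        _, draws, _ = small_fit
        a = draws.arrays["FWL[sim001]"]
        assert a.shape == (QUICK.chains, QUICK.samples // QUICK.thin)

    def test_seed_determinism(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=2, tdf=tdf,
                                               seed=4)
        model = build_model(source_panel, consumers, tdf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = run_mcmc(model, QUICK)
            d2 = run_mcmc(model, QUICK)
        assert all(np.array_equal(d1.arrays[k], d2.arrays[k])
                   for k in d1.arrays)

    def test_drawwise_identities(self, small_fit):
        model, draws, _ = small_fit
        for cid in model.consumer_ids:
            f = np.stack([draws.draws(f"f[{cid},{g}]")
                          for g in model.groups])
            assert np.allclose(f.sum(axis=0), 1.0, atol=1e-9)
            assert np.all(f >= 0)
            pts = draws.draws(f"PTS[{cid}]")
            fwl = draws.draws(f"FWL[{cid}]")
            mts = draws.draws(f"MTS[{cid}]")
            assert np.allclose(pts, fwl - mts, atol=0)

    def test_truncation_flag_keeps_draws_nonnegative(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=2, tdf=tdf,
                                               seed=5)
        config = default_model_config(truncate_at_zero=True)
        model = build_model(source_panel, consumers, tdf, config=config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = run_mcmc(model, QUICK)
        for cid in model.consumer_ids:
            assert (draws.draws(f"FWL[{cid}]") >= 0).all()
            assert (draws.draws(f"MTS[{cid}]") >= 0).all()
            assert (draws.draws(f"PTS[{cid}]") >= 0).all()

    def test_diagnostics_attached(self, small_fit):
        _, draws, _ = small_fit
        assert set(draws.rhat) == set(draws.parameters)
        assert all(np.isfinite(v) for v in draws.rhat.values())

    def test_informative_prior_pulls_posterior(self, source_panel, tdf):
        consumers, _ = omsm.simulate_consumers(source_panel, n=1, tdf=tdf,
                                               seed=6)
        target = 30.0  # far from the empirical Phe mean of ~0 ‰
        priors = PriorConfig(mu_informative={("Phe", "surface"): (target, 0.1)})
        model = build_model(source_panel, consumers, tdf, priors=priors)
        base_model = build_model(source_panel, consumers, tdf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with_prior = run_mcmc(model, QUICK).draws("mu[Phe,surface]").mean()
            without = run_mcmc(base_model, QUICK).draws("mu[Phe,surface]").mean()
        assert with_prior > without + 1.0

    def test_long_format_export_roundtrip(self, small_fit):
        _, draws, _ = small_fit
        df = draws.to_frame()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        piv = df[df.parameter == "FWL[sim001]"].pivot(
            index="chain", columns="iteration", values="value"
        )
        assert np.array_equal(piv.to_numpy(), draws.arrays["FWL[sim001]"])

    def test_inference_data_container(self, small_fit):
        _, draws, _ = small_fit
        idata = draws.to_inference_data()
        assert "FWL[sim001]" in idata.posterior


class TestSourcePosterior:
    def test_vague_posterior_tracks_sample_mean(self, tdf):
        """With many source replicates the posterior of a source mean must
        concentrate at the sample mean (closed-form normal-model limit)."""
        rng = np.random.default_rng(11)
        big = pd.DataFrame({
            "Phe": rng.normal(5, 1, 400),
            "Pro": rng.normal(8, 1, 400),
            "Glx": rng.normal(9, 1, 400),
        })
        sources = SourceDataset({"only": big})
        config = ModelConfig(roles={"Phe": "mixing", "Pro": "trophic_fwl",
                                    "Glx": "trophic_mts"})
        consumer = omsm.ConsumerSample(
            "c1", {"Phe": 5.2, "Pro": 14.0, "Glx": 13.0},
            {"Phe": 0.5, "Pro": 0.5, "Glx": 0.5},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = build_model(sources, [consumer], tdf, config=config)
            draws = run_mcmc(model, MCMCConfig(chains=3, adapt=1000,
                                               burn_in=1000, samples=4000,
                                               thin=4, seed=5))
        x = draws.draws("mu[Phe,only]")
        mcse = x.std() / np.sqrt(max(draws.ess["mu[Phe,only]"], 1.0))
        assert abs(x.mean() - big["Phe"].mean()) < 2 * mcse + 1e-3
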