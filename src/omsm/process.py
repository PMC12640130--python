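"""Deterministic forward equations of the organic-matter supply model.

These pure functions implement the process model shared by the MCMC
likelihood and the data simulator:

- linear delta-space mixing of basal sources into a food-web base value;
- plug-in estimators for food-web length (FWL, from a constant-discrimination
  tracer) and metazoan trophic steps (MTS, from a variable-discrimination
  tracer), with PTS = FWL − MTS protozoan steps by definition;
- the per-class trophic-discrimination offsets mapping base values to
  expected consumer values;
- the printed relative-error propagation formulas for trophic-parameter and
  consumer-tracer uncertainties.

All tracer values are delta15N in ‰; trophic parameters are in trophic steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import OMSMWarning, TracerSpec

__all__ = [
    "FoodWebState",
    "TrophicEstimate",
    "apply_discrimination",
    "consumer_sd",
    "food_web_length",
    "forward_model",
    "metazoan_steps",
    "mix_base",
    "trophic_uncertainty",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class FoodWebState:
    """Mixing coefficients and trophic-step counts for one consumer.

    ``f`` lies on the probability simplex; ``PTS = FWL − MTS`` exactly.
    ``mu_base`` optionally carries the per-tracer base-of-food-web values (‰)
    implied by ``f``.
    """

    f: np.ndarray
    FWL: float
    MTS: float
    mu_base: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        _check_simplex(f)
        object.__setattr__(self, "f", f)

    @property
    def PTS(self) -> float:
        return self.FWL - self.MTS


@dataclass(frozen=True)
class TrophicEstimate:
    """A trophic-parameter estimate (mean, SD) in trophic steps."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _check_simplex(f: np.ndarray) -> None:
    if np.any(f < -_SIMPLEX_TOL) or abs(float(np.sum(f)) - 1.0) > _SIMPLEX_TOL:
        raise ValueError(
            f"mixing coefficients must be a probability simplex vector; got {f!r}"
        )


def mix_base(f: Sequence[float], source_means: np.ndarray) -> np.ndarray:
    """Linear delta-space mixture of source means.

    Parameters
    ----------
    f:
        Mixing coefficients over sources (simplex vector, length n_sources).
    source_means:
        Per-source tracer means, shape (n_sources,) for a single tracer or
        (n_sources, n_tracers).

    Returns the convex combination per tracer: ``mu_base = sum_i f_i mu_{j,i}``.
    """
    f = np.asarray(f, dtype=float)
    _check_simplex(f)
    means = np.asarray(source_means, dtype=float)
    if means.shape[0] != f.shape[0]:
        raise ValueError(
            f"{f.shape[0]} mixing coefficients for {means.shape[0]} source means"
        )
    return np.tensordot(f, means, axes=(0, 0))


def food_web_length(delta_consumer: float, mu_base: float, tdf: TracerSpec) -> float:
    """Plug-in food-web length from a constant-discrimination trophic tracer.

    ``(delta_consumer − mu_base) / Δ_meta`` — the number of trophic steps a
    uniform per-step enrichment of Δ_meta would need to carry the base value
    to the consumer value.
    """
    if tdf.delta_meta == 0:
        raise ZeroDivisionError(
            f"tracer {tdf.name}: zero trophic discrimination factor"
        )
    return (delta_consumer - mu_base) / tdf.delta_meta


def metazoan_steps(delta_consumer: float, mu_base: float, tdf: TracerSpec) -> float:
    """Plug-in metazoan trophic steps from a variable-discrimination tracer.

    ``(delta_consumer − mu_base) / Δ_meta`` for a tracer that fractionates
    only (or predominantly) during metazoan steps.
    """
    if tdf.delta_meta == 0:
        raise ZeroDivisionError(
            f"tracer {tdf.name}: zero metazoan trophic discrimination factor"
        )
    return (delta_consumer - mu_base) / tdf.delta_meta


def trophic_uncertainty(
    mu: float,
    delta_consumer: float,
    sigma_delta_consumer: float,
    tdf_value: float,
    tdf_sigma: float,
) -> float:
    """SD of a trophic-parameter estimate by relative-error quadrature.

    Returns ``|mu| * sqrt((sigma_delta_consumer/delta_consumer)^2 +
    (tdf_sigma/tdf_value)^2)``, the standard propagation formula applied to
    the ratio estimators above, exactly as conventionally printed (the
    relative error of the measured consumer delta value is taken against its
    absolute value on the delta scale).

    A warning names the offending term when a denominator is near zero:
    the formula degenerates as the consumer delta value approaches 0 ‰.
    """
    if abs(tdf_value) < 1e-6:
        raise ZeroDivisionError("trophic discrimination factor is (near) zero")
    if abs(delta_consumer) < 1.0:
        warnings.warn(
            "trophic_uncertainty: |delta_consumer| < 1 ‰; the relative-error "
            f"term sigma/delta = {sigma_delta_consumer}/{delta_consumer} is "
            "unstable this close to 0 ‰",
            OMSMWarning,
            stacklevel=2,
        )
    if abs(delta_consumer) == 0:
        raise ZeroDivisionError("consumer delta value is zero")
    rel = np.hypot(sigma_delta_consumer / delta_consumer, tdf_sigma / tdf_value)
    return abs(mu) * float(rel)


def apply_discrimination(
    mu_base: float | np.ndarray, state: FoodWebState, tdf: TracerSpec
) -> float | np.ndarray:
    """Expected consumer value for one tracer given base value and trophic state.

    conservative: ``mu_base``; constant: ``mu_base + FWL*Δ``; variable:
    ``mu_base + PTS*Δ_proto + MTS*Δ_meta``.
    """
    if tdf.discrimination_class == "conservative":
        return mu_base
    if tdf.discrimination_class == "constant":
        return mu_base + state.FWL * tdf.delta_meta
    return mu_base + state.PTS * tdf.delta_proto + state.MTS * tdf.delta_meta


def consumer_sd(
    alpha: float, state: FoodWebState, tdf: TracerSpec
) -> float:
    """Total SD of the expected consumer value for one tracer.

    Combines analytical uncertainty with Δ¹⁵N uncertainty scaled by the
    trophic-step counts, in quadrature: conservative tracers keep ``alpha``;
    constant tracers add ``FWL*σ(Δ)``; variable tracers add ``PTS*σ(Δ_proto)``
    and ``MTS*σ(Δ_meta)`` as separate terms.
    """
    if not alpha > 0:
        raise ValueError("analytical SD alpha must be > 0")
    if tdf.discrimination_class == "conservative":
        return float(alpha)
    if tdf.discrimination_class == "constant":
        return float(np.hypot(alpha, state.FWL * tdf.sigma_delta_meta))
    return float(
        np.sqrt(
            alpha**2
            + (state.PTS * tdf.sigma_delta_proto) ** 2
            + (state.MTS * tdf.sigma_delta_meta) ** 2
        )
    )


def forward_model(
    f: Sequence[float],
    PTS: float,
    MTS: float,
    source_means: "np.ndarray | Mapping[str, Sequence[float]]",
    tdf_table: Mapping[str, TracerSpec],
) -> dict[str, float]:
    """Predicted consumer values for all tracers (the full process model).

    Composes :func:`mix_base` with :func:`apply_discrimination` per tracer:
    ``mu_{j,k} = sum_i f_i mu_{j,i} + PTS*Δ_{j,proto} + MTS*Δ_{j,meta}`` with
    the per-class reductions.  Linear (affine) in ``f`` at fixed PTS/MTS.

    ``source_means`` maps tracer name -> per-source means (‰), or is an
    array of shape (n_sources, n_tracers) ordered like ``tdf_table``.
    """
    names = list(tdf_table)
    if isinstance(source_means, Mapping):
        means = np.column_stack([np.asarray(source_means[j], float) for j in names])
    else:
        means = np.asarray(source_means, dtype=float)
        if means.ndim != 2 or means.shape[1] != len(names):
            raise ValueError(
                "source_means must be (n_sources, n_tracers) matching tdf_table"
            )
    base = mix_base(f, means)
    state = FoodWebState(f=np.asarray(f, float), FWL=PTS + MTS, MTS=MTS)
    return {
        j: float(apply_discrimination(base[idx], state, tdf_table[j]))
        for idx, j in enumerate(names)
    }
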