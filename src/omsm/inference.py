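"""Prior specification and MCMC estimation of the joint posterior.

The model graph
---------------
Source replicates for tracer ``j`` in group ``i`` are modelled as
``X_{j,i} ~ Normal(mu_{j,i}, sigma_{j,i})`` with a flat prior on the mean and
(by default) a vague gamma prior on the precision ``1/sigma^2``.  Each
consumer ``k`` carries a Dirichlet-distributed mixing vector ``f_k`` over
sources; the base-of-food-web value of every tracer is the linear mixture
``mu_{j,k,base} = sum_i f_{i,k} mu_{j,i}``.  Food-web length and metazoan
trophic steps are latent variables with normal densities centred on the
plug-in ratio estimators (consumer value minus base value over the tracer's
discrimination factor) and SDs from relative-error propagation; protozoan
steps are ``PTS_k = FWL_k − MTS_k`` by definition.  Each mixing tracer then
contributes ``Y_{j,k} ~ Normal(mu_{j,k}, sigma_{j,k})`` with the
class-dependent discrimination offset and uncertainty.

Because trophic-step counts multiply the discrimination factors inside the
mixing likelihood, the mixing and trophic sub-models must be solved jointly;
that interdependence is the whole point of the model.

The sampler
-----------
A seeded, adaptive Metropolis-within-Gibbs kernel: source precisions are
drawn from their conjugate gamma conditionals; source means are updated by
per-tracer random-walk Metropolis (their conditionals factorise across
tracers); each consumer's mixing vector moves via a symmetric random walk in
additive-log-ratio space (with the simplex Jacobian in the target); FWL and
MTS move by scalar random walks, vectorised across consumers.  Proposal
scales adapt toward standard acceptance targets during the adaptation phase
only, so the post-adaptation chain is a valid fixed-kernel Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import (
    ConsumerSample,
    ModelConfig,
    OMSMWarning,
    SourceDataset,
    TDFTable,
    effective_specs,
    validate_config,
)

__all__ = [
    "MCMCConfig",
    "OMSModel",
    "PosteriorDraws",
    "PriorConfig",
    "build_model",
    "log_posterior",
    "run_mcmc",
]

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-9  # floor on propagated trophic SDs to keep densities finite


@dataclass
class PriorConfig:
    """Prior settings.

    mu_bounds:
        Uniform prior bounds (‰) on every source tracer mean (default
        −100 to 100, effectively flat over the physical delta15N range).
    dispersion_gamma:
        (shape, rate) of the vague gamma prior on source dispersions
        (default 0.001, 0.001).
    dirichlet_alpha:
        Concentration vector for the mixing-coefficient prior; ``None``
        means the uniform Dirichlet (all ones).
    sigma_prior_on:
        ``"precision"`` places the gamma prior on 1/sigma^2 (the standard
        BUGS encoding of a vague dispersion prior); ``"sigma"`` places it
        literally on sigma.
    mu_informative:
        Optional informative overrides: (tracer, group) -> (mean, sd) of a
        normal prior replacing the uniform for that source mean.
    """

    mu_bounds: tuple[float, float] = (-100.0, 100.0)
    dispersion_gamma: tuple[float, float] = (0.001, 0.001)
    dirichlet_alpha: np.ndarray | None = None
    sigma_prior_on: str = "precision"
    mu_informative: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        lo, hi = self.mu_bounds
        if not lo < hi:
            raise ValueError("mu_bounds must satisfy low < high")
        a, b = self.dispersion_gamma
        if not (a > 0 and b > 0):
            raise ValueError("gamma shape and rate must be > 0")
        if self.sigma_prior_on not in ("precision", "sigma"):
            raise ValueError("sigma_prior_on must be 'precision' or 'sigma'")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
            if np.any(alpha <= 0):
                raise ValueError("dirichlet_alpha components must be > 0")
            self.dirichlet_alpha = alpha


@dataclass
class MCMCConfig:
    """MCMC run settings: 3 chains of 5,000 adaptation, 10,000 burn-in and
    10,000 sampling steps thinned by 10, by default."""

    chains: int = 3
    adapt: int = 5_000
    burn_in: int = 10_000
    samples: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chains", "adapt", "burn_in", "samples", "thin"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.samples % self.thin != 0:
            raise ValueError("thin must divide evenly into samples")

    @property
    def retained_per_chain(self) -> int:
        return self.samples // self.thin


class OMSModel:
    """Declarative model description bound to data, ready for sampling.

    Built by :func:`build_model`.  Holds the design (tracer order, class
    codes, discrimination parameters), the data as dense arrays, and the
    prior settings; exposes :meth:`log_posterior` over natural parameters.
    """

    def __init__(
        self,
        sources: SourceDataset,
        consumers: Sequence[ConsumerSample],
        tdf: TDFTable,
        priors: PriorConfig,
        config: ModelConfig,
        *,
        fix_source_params: bool = False,
        prior_only: bool = False,
    ) -> None:
        report = validate_config(config, sources, consumers, tdf)
        if not report.ok:
            raise ValueError(
                "model configuration invalid:\n  " + "\n  ".join(report.errors)
            )
        self.config = config
        self.priors = priors
        self.specs = effective_specs(config, tdf)
        self.tracers = list(self.specs)  # mixing first, then fwl, mts
        self.groups = list(sources.groups)
        self.consumer_ids = [c.id for c in consumers]
        self.fix_source_params = bool(fix_source_params)
        self.prior_only = bool(prior_only)
        self.truncate = bool(config.truncate_at_zero)

        n_j, n_i, n_k = len(self.tracers), len(self.groups), len(consumers)
        self.n_tracers, self.n_sources, self.n_consumers = n_j, n_i, n_k

        # tracer design arrays
        specs = [self.specs[j] for j in self.tracers]
        self.dm = np.array([s.delta_meta for s in specs])
        self.sdm = np.array([s.sigma_delta_meta for s in specs])
        self.dp = np.array([s.delta_proto for s in specs])
        self.sdp = np.array([s.sigma_delta_proto for s in specs])
        self.cls = np.array(
            [("conservative", "constant", "variable").index(s.discrimination_class)
             for s in specs]
        )
        self.mix_idx = np.array(
            [idx for idx, j in enumerate(self.tracers)
             if config.role_of(j) == "mixing"]
        )
        self.jF = self.tracers.index(config.fwl_tracer)
        self.jM = self.tracers.index(config.mts_tracer)

        # source data sufficient statistics
        self.n_rep = np.array([sources.n_replicates(g) for g in self.groups])
        self.sum_x = np.zeros((n_j, n_i))
        self.sum_x2 = np.zeros((n_j, n_i))
        for c_i, g in enumerate(self.groups):
            x = sources.samples[g][self.tracers].to_numpy(dtype=float)
            self.sum_x[:, c_i] = x.sum(axis=0)
            self.sum_x2[:, c_i] = (x**2).sum(axis=0)
        self.source_means = self.sum_x / self.n_rep  # (n_j, n_i)
        mean_sq = self.source_means**2
        ss = self.sum_x2 - self.n_rep * mean_sq
        with np.errstate(invalid="ignore"):
            self.source_sds = np.sqrt(np.maximum(ss / (self.n_rep - 1), 0.0))
        self.source_sds = np.maximum(self.source_sds, 0.05)

        # consumer data
        self.Y = np.array(
            [[c.values[j] for j in self.tracers] for c in consumers]
        )  # (n_k, n_j)
        self.A = np.array(
            [[c.alpha[j] for j in self.tracers] for c in consumers]
        )

        self.alpha_dir = (
            priors.dirichlet_alpha
            if priors.dirichlet_alpha is not None
            else np.ones(n_i)
        )
        if self.alpha_dir.shape != (n_i,):
            raise ValueError(
                f"dirichlet_alpha must have length {n_i} (one per source)"
            )
        self._log_beta_dir = float(
            gammaln(self.alpha_dir).sum() - gammaln(self.alpha_dir.sum())
        )
        # informative normal priors on selected source means
        self._mu_inf_mean = np.full((n_j, n_i), np.nan)
        self._mu_inf_sd = np.full((n_j, n_i), np.nan)
        for (aa, grp), (m, s) in dict(priors.mu_informative).items():
            if aa in self.tracers and grp in self.groups:
                r, c = self.tracers.index(aa), self.groups.index(grp)
                self._mu_inf_mean[r, c] = m
                self._mu_inf_sd[r, c] = s

    # ------------------------------------------------------------------ #
    # density components (vectorised; all return per-unit arrays)

    def _source_loglik_per_tracer(self, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Sum over groups of the normal source-data log-likelihood, per tracer."""
        ss = self.sum_x2 - 2.0 * mu * self.sum_x + self.n_rep * mu**2
        ll = (
            -0.5 * self.n_rep * _LOG2PI
            - self.n_rep * np.log(sigma)
            - 0.5 * ss / sigma**2
        )
        return ll.sum(axis=1)

    def _trophic_moments(self, base: np.ndarray) -> tuple[np.ndarray, ...]:
        """Means and SDs of the FWL and MTS latent densities, per consumer."""
        yF, yM = self.Y[:, self.jF], self.Y[:, self.jM]
        mF = (yF - base[:, self.jF]) / self.dm[self.jF]
        mM = (yM - base[:, self.jM]) / self.dm[self.jM]
        with np.errstate(divide="ignore", invalid="ignore"):
            relF = np.hypot(self.A[:, self.jF] / yF, self.sdm[self.jF] / self.dm[self.jF])
            relM = np.hypot(self.A[:, self.jM] / yM, self.sdm[self.jM] / self.dm[self.jM])
        sF = np.maximum(np.abs(mF) * relF, _SIGMA_FLOOR)
        sM = np.maximum(np.abs(mM) * relM, _SIGMA_FLOOR)
        return mF, sF, mM, sM

    @staticmethod
    def _norm_logpdf(x, m, s):
        return -0.5 * _LOG2PI - np.log(s) - 0.5 * ((x - m) / s) ** 2

    def _mixing_loglik_matrix(
        self, base: np.ndarray, FWL: np.ndarray, MTS: np.ndarray
    ) -> np.ndarray:
        """Mixing-tracer log-likelihood terms, shape (n_k, n_mix)."""
        if self.prior_only or self.mix_idx.size == 0:
            return np.zeros((self.n_consumers, 0))
        m = self.mix_idx
        PTS = FWL - MTS
        mean = (
            base[:, m]
            + PTS[:, None] * self.dp[m][None, :]
            + MTS[:, None] * self.dm[m][None, :]
        )
        var_troph = np.where(
            self.cls[m][None, :] == 1,
            (FWL[:, None] * self.sdm[m][None, :]) ** 2,
            (PTS[:, None] * self.sdp[m][None, :]) ** 2
            + (MTS[:, None] * self.sdm[m][None, :]) ** 2,
        )
        sd = np.sqrt(self.A[:, m] ** 2 + var_troph)
        return self._norm_logpdf(self.Y[:, m], mean, sd)

    def _consumer_logpost(
        self, f: np.ndarray, FWL: np.ndarray, MTS: np.ndarray, mu: np.ndarray
    ) -> np.ndarray:
        """Per-consumer joint terms: Dirichlet prior + trophic latents + mixing
        likelihood.  Returns shape (n_k,); −inf where support is violated."""
        out = np.where(
            np.all(f > 0, axis=1), ((self.alpha_dir - 1.0) * np.log(
                np.clip(f, 1e-300, None))).sum(axis=1) - self._log_beta_dir,
            -np.inf,
        )
        base = f @ mu.T  # (n_k, n_j)
        mF, sF, mM, sM = self._trophic_moments(base)
        out = out + self._norm_logpdf(FWL, mF, sF) + self._norm_logpdf(MTS, mM, sM)
        out = out + self._mixing_loglik_matrix(base, FWL, MTS).sum(axis=1)
        if self.truncate:
            bad = (FWL < 0) | (MTS < 0) | (FWL - MTS < 0)
            out = np.where(bad, -np.inf, out)
        return out

    def _tracer_logpost(
        self, mu: np.ndarray, sigma: np.ndarray, f: np.ndarray,
        FWL: np.ndarray, MTS: np.ndarray,
    ) -> np.ndarray:
        """Per-tracer terms involving mu[j, :]: source likelihood plus the
        consumer-side terms attributable to tracer j.  Shape (n_j,)."""
        out = self._source_loglik_per_tracer(mu, sigma)
        lo, hi = self.priors.mu_bounds
        out = np.where(
            np.all((mu >= lo) & (mu <= hi), axis=1), out, -np.inf
        )
        inf = ~np.isnan(self._mu_inf_mean)
        if inf.any():
            lp = np.where(
                inf,
                self._norm_logpdf(
                    mu,
                    np.where(inf, self._mu_inf_mean, 0.0),
                    np.where(inf, self._mu_inf_sd, 1.0),
                ),
                0.0,
            )
            out = out + lp.sum(axis=1)
        base = f @ mu.T
        mF, sF, mM, sM = self._trophic_moments(base)
        out[self.jF] += self._norm_logpdf(FWL, mF, sF).sum()
        out[self.jM] += self._norm_logpdf(MTS, mM, sM).sum()
        mix = self._mixing_loglik_matrix(base, FWL, MTS)
        if mix.shape[1]:
            out[self.mix_idx] += mix.sum(axis=0)
        return out

    def _sigma_logprior(self, sigma: np.ndarray) -> np.ndarray:
        a, b = self.priors.dispersion_gamma
        if self.priors.sigma_prior_on == "precision":
            tau = sigma**-2
            # gamma density in tau plus |d tau / d sigma| Jacobian
            return (
                a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(tau) - b * tau
                + np.log(2.0) - 3.0 * np.log(sigma)
            )
        return a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(sigma) - b * sigma

    # ------------------------------------------------------------------ #

    def log_posterior(self, point: Mapping[str, np.ndarray]) -> float:
        """Joint log prior × likelihood (up to a constant) at ``point``.

        ``point`` maps ``"mu"``/``"sigma"`` to (n_tracers, n_sources) arrays,
        ``"f"`` to (n_consumers, n_sources), and ``"FWL"``/``"MTS"`` to
        (n_consumers,) arrays.  Returns −inf outside the support (f off the
        simplex, sigma ≤ 0, mu outside its uniform bounds).
        """
        mu = np.asarray(point["mu"], float)
        sigma = np.asarray(point["sigma"], float)
        f = np.asarray(point["f"], float)
        FWL = np.asarray(point["FWL"], float)
        MTS = np.asarray(point["MTS"], float)
        if np.any(sigma <= 0):
            return -np.inf
        if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-9):
            return -np.inf
        lo, hi = self.priors.mu_bounds
        if np.any(mu < lo) or np.any(mu > hi):
            return -np.inf
        total = float(self._sigma_logprior(sigma).sum())
        total += float(self._tracer_logpost(mu, sigma, f, FWL, MTS).sum())
        # _tracer_logpost already contains the consumer-side terms; add the
        # Dirichlet prior which it does not include
        fc = np.clip(f, 1e-300, None)
        total += float(
            ((self.alpha_dir - 1.0) * np.log(fc)).sum()
            - self.n_consumers * self._log_beta_dir
        )
        if self.truncate and np.any((FWL < 0) | (MTS < 0) | (FWL - MTS < 0)):
            return -np.inf
        return total

    def initial_state(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Plug-in initialisation: empirical source statistics, centroid
        mixing vectors, ratio-estimator trophic steps, with a small jitter."""
        n_j, n_i, n_k = self.n_tracers, self.n_sources, self.n_consumers
        mu = self.source_means + rng.normal(0, 0.02, (n_j, n_i))
        sigma = self.source_sds * np.exp(rng.normal(0, 0.02, (n_j, n_i)))
        z = rng.normal(0, 0.05, (n_k, n_i - 1)) if n_i > 1 else np.zeros((n_k, 0))
        f = _alr_inverse(z)
        base = f @ mu.T
        FWL = (self.Y[:, self.jF] - base[:, self.jF]) / self.dm[self.jF]
        MTS = (self.Y[:, self.jM] - base[:, self.jM]) / self.dm[self.jM]
        FWL = FWL + rng.normal(0, 0.02, n_k)
        MTS = MTS + rng.normal(0, 0.02, n_k)
        if self.truncate:
            MTS = np.clip(MTS, 0.0, None)
            FWL = np.clip(FWL, MTS, None)
        return {"mu": mu, "sigma": sigma, "z": z, "FWL": FWL, "MTS": MTS}

    def describe(self) -> dict[str, object]:
        """Structural summary of the model graph."""
        return {
            "tracers": list(self.tracers),
            "groups": list(self.groups),
            "consumers": list(self.consumer_ids),
            "mixing_tracers": [self.tracers[i] for i in self.mix_idx],
            "fwl_tracer": self.tracers[self.jF],
            "mts_tracer": self.tracers[self.jM],
            "n_simplex_dim": self.n_sources,
            "n_trophic_latents_per_consumer": 2,
            "n_mixing_likelihood_terms": int(self.mix_idx.size) * self.n_consumers,
            "fix_source_params": self.fix_source_params,
            "prior_only": self.prior_only,
        }


def _alr_inverse(z: np.ndarray) -> np.ndarray:
    """Additive-log-ratio inverse: map (n_k, n_i−1) to simplex (n_k, n_i)."""
    zfull = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    return np.exp(zfull - logsumexp(zfull, axis=1, keepdims=True))


def build_model(
    sources: SourceDataset,
    consumers: Sequence[ConsumerSample],
    tdf: TDFTable,
    priors: PriorConfig | None = None,
    config: ModelConfig | None = None,
    *,
    fix_source_params: bool = False,
    prior_only: bool = False,
) -> OMSModel:
    """Assemble the model graph for the given data and configuration.

    ``fix_source_params`` pins source means/SDs at their sample statistics
    instead of sampling them (useful for small problems and oracle
    comparisons); ``prior_only`` drops the mixing-tracer likelihood so the
    prior (and the trophic latent structure) can be sampled on its own.
    """
    from .core import default_model_config

    priors = priors if priors is not None else PriorConfig()
    config = config if config is not None else default_model_config()
    return OMSModel(
        sources, consumers, tdf, priors, config,
        fix_source_params=fix_source_params, prior_only=prior_only,
    )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, indexed (chain, draw), plus diagnostics.

    ``arrays`` maps parameter names (``f[k,src]``, ``FWL[k]``, ``MTS[k]``,
    ``PTS[k]``, ``mu[aa,src]``, ``sigma[aa,src]``, ``mu_base[aa,k]``) to
    arrays of shape (chains, draws).  ``rhat``/``ess`` map the same names to
    split-R̂ and effective sample size; ``converged`` is False if any
    parameter fails R̂ < 1.05 or ESS > 200.
    """

    arrays: dict[str, np.ndarray]
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    rhat_threshold: float = 1.05
    ess_threshold: float = 200.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.arrays.values()}
        if len(shapes) > 1:
            raise ValueError(f"unequal draw shapes across parameters: {shapes}")

    @property
    def parameters(self) -> list[str]:
        return list(self.arrays)

    def draws(self, name: str, pooled: bool = True) -> np.ndarray:
        a = self.arrays[name]
        return a.reshape(-1) if pooled else a

    @property
    def n_draws(self) -> int:
        a = next(iter(self.arrays.values()))
        return a.shape[0] * a.shape[1]

    @property
    def flagged(self) -> list[str]:
        out = []
        for name in self.rhat:
            if (self.rhat[name] > self.rhat_threshold
                    or self.ess.get(name, np.inf) < self.ess_threshold):
                out.append(name)
        return out

    @property
    def converged(self) -> bool:
        return not self.flagged

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        rows = []
        for name, a in self.arrays.items():
            n_chain, n_draw = a.shape
            rows.append(
                pd.DataFrame({
                    "chain": np.repeat(np.arange(n_chain), n_draw),
                    "iteration": np.tile(np.arange(n_draw), n_chain),
                    "parameter": name,
                    "value": a.reshape(-1),
                })
            )
        return pd.concat(rows, ignore_index=True)

    def to_inference_data(self):
        """Package the draws as an ``arviz.InferenceData`` container."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.arrays.items()})


def _compute_diagnostics(arrays: dict[str, np.ndarray]) -> tuple[dict, dict]:
    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, a in arrays.items():
            if np.ptp(a) == 0:  # constant (e.g. fixed source params)
                rhat[name] = 1.0
                ess[name] = float(a.size)
                continue
            da = az.convert_to_dataset({"x": a})
            rhat[name] = float(az.rhat(da)["x"].values)
            ess[name] = float(az.ess(da)["x"].values)
            if np.isnan(rhat[name]):
                rhat[name] = 1.0
    return rhat, ess


def run_mcmc(model: OMSModel, config: MCMCConfig | None = None) -> PosteriorDraws:
    """Sample the joint posterior with the adaptive Metropolis-within-Gibbs
    kernel.  Reproducible given ``config.seed``; attaches split-R̂ and ESS
    diagnostics and warns (never silently ignores) when any parameter fails
    the R̂ < 1.05 / ESS > 200 thresholds.
    """
    config = config if config is not None else MCMCConfig()
    n_j, n_i, n_k = model.n_tracers, model.n_sources, model.n_consumers
    retained = config.retained_per_chain

    store = {
        "mu": np.empty((config.chains, retained, n_j, n_i)),
        "sigma": np.empty((config.chains, retained, n_j, n_i)),
        "f": np.empty((config.chains, retained, n_k, n_i)),
        "FWL": np.empty((config.chains, retained, n_k)),
        "MTS": np.empty((config.chains, retained, n_k)),
    }

    for chain in range(config.chains):
        rng = np.random.default_rng([int(config.seed) % (2**31), chain])
        _run_chain(model, config, rng, chain, store)

    # assemble named scalar arrays
    arrays: dict[str, np.ndarray] = {}
    for r, aa in enumerate(model.tracers):
        for c, g in enumerate(model.groups):
            arrays[f"mu[{aa},{g}]"] = store["mu"][:, :, r, c]
            arrays[f"sigma[{aa},{g}]"] = store["sigma"][:, :, r, c]
    for k, cid in enumerate(model.consumer_ids):
        for c, g in enumerate(model.groups):
            arrays[f"f[{cid},{g}]"] = store["f"][:, :, k, c]
        arrays[f"FWL[{cid}]"] = store["FWL"][:, :, k]
        arrays[f"MTS[{cid}]"] = store["MTS"][:, :, k]
        arrays[f"PTS[{cid}]"] = store["FWL"][:, :, k] - store["MTS"][:, :, k]
    # derived base-of-food-web values, draw-wise
    mu_base = np.einsum("cdki,cdji->cdkj", store["f"], store["mu"])
    for k, cid in enumerate(model.consumer_ids):
        for r, aa in enumerate(model.tracers):
            arrays[f"mu_base[{aa},{cid}]"] = mu_base[:, :, k, r]

    rhat, ess = _compute_diagnostics(arrays)
    draws = PosteriorDraws(arrays=arrays, rhat=rhat, ess=ess)
    if not draws.converged:
        warnings.warn(
            f"convergence diagnostics failed for {len(draws.flagged)} "
            f"parameter(s): {draws.flagged[:5]}{'...' if len(draws.flagged) > 5 else ''} "
            "(split-Rhat > 1.05 or ESS < 200); summaries may be unreliable",
            OMSMWarning,
            stacklevel=2,
        )
    return draws


def _run_chain(model, config, rng, chain, store):
    n_j, n_i, n_k = model.n_tracers, model.n_sources, model.n_consumers
    st = model.initial_state(rng)
    mu, sigma, z, FWL, MTS = st["mu"], st["sigma"], st["z"], st["FWL"], st["MTS"]
    f = _alr_inverse(z)

    # proposal scales and acceptance trackers
    s_mu = np.full((n_j, n_i), 0.3)
    s_f = np.full(n_k, 0.5)
    s_F = np.full(n_k, 0.3)
    s_M = np.full(n_k, 0.3)
    acc = {key: np.zeros_like(v) for key, v in
           (("mu", s_mu), ("f", s_f), ("F", s_F), ("M", s_M))}
    adapt_interval = 50

    a0, b0 = model.priors.dispersion_gamma
    use_gibbs_sigma = model.priors.sigma_prior_on == "precision"
    lo, hi = model.priors.mu_bounds

    def jac(fm):  # ALR Jacobian: sum of log components
        return np.log(np.clip(fm, 1e-300, None)).sum(axis=1)

    total_steps = config.adapt + config.burn_in + config.samples
    keep_from = config.adapt + config.burn_in
    out_idx = 0

    cur_consumer = model._consumer_logpost(f, FWL, MTS, mu) + jac(f)

    for step in range(total_steps):
        adapting = step < config.adapt

        if not model.fix_source_params:
            # -- sigma: conjugate Gibbs on precision, or MH on log sigma
            ss = model.sum_x2 - 2.0 * mu * model.sum_x + model.n_rep * mu**2
            if use_gibbs_sigma:
                shape = a0 + model.n_rep / 2.0
                rate = b0 + ss / 2.0
                tau = rng.gamma(shape, 1.0 / rate)
                sigma = 1.0 / np.sqrt(tau)
            else:
                prop = sigma * np.exp(0.2 * rng.standard_normal((n_j, n_i)))
                cur = (-model.n_rep * np.log(sigma) - 0.5 * ss / sigma**2
                       + model._sigma_logprior(sigma) + np.log(sigma))
                new = (-model.n_rep * np.log(prop) - 0.5 * ss / prop**2
                       + model._sigma_logprior(prop) + np.log(prop))
                take = np.log(rng.random((n_j, n_i))) < new - cur
                sigma = np.where(take, prop, sigma)

            # -- mu: per-tracer random-walk MH, one sweep per source group
            for c_i in range(n_i):
                prop = mu.copy()
                prop[:, c_i] = mu[:, c_i] + s_mu[:, c_i] * rng.standard_normal(n_j)
                cur_t = model._tracer_logpost(mu, sigma, f, FWL, MTS)
                new_t = model._tracer_logpost(prop, sigma, f, FWL, MTS)
                take = np.log(rng.random(n_j)) < new_t - cur_t
                mu[take, c_i] = prop[take, c_i]
                acc["mu"][:, c_i] += take
            cur_consumer = model._consumer_logpost(f, FWL, MTS, mu) + jac(f)

        # -- f: logistic-normal (ALR random-walk) proposal per consumer
        if n_i > 1:
            z_prop = z + s_f[:, None] * rng.standard_normal((n_k, n_i - 1))
            f_prop = _alr_inverse(z_prop)
            new_c = model._consumer_logpost(f_prop, FWL, MTS, mu) + jac(f_prop)
            take = np.log(rng.random(n_k)) < new_c - cur_consumer
            z[take] = z_prop[take]
            f[take] = f_prop[take]
            cur_consumer[take] = new_c[take]
            acc["f"] += take

        # -- FWL: scalar random walk per consumer
        F_prop = FWL + s_F * rng.standard_normal(n_k)
        new_c = model._consumer_logpost(f, F_prop, MTS, mu) + jac(f)
        take = np.log(rng.random(n_k)) < new_c - cur_consumer
        FWL = np.where(take, F_prop, FWL)
        cur_consumer = np.where(take, new_c, cur_consumer)
        acc["F"] += take

        # -- MTS: scalar random walk per consumer
        M_prop = MTS + s_M * rng.standard_normal(n_k)
        new_c = model._consumer_logpost(f, FWL, M_prop, mu) + jac(f)
        take = np.log(rng.random(n_k)) < new_c - cur_consumer
        MTS = np.where(take, M_prop, MTS)
        cur_consumer = np.where(take, new_c, cur_consumer)
        acc["M"] += take

        if adapting and (step + 1) % adapt_interval == 0:
            for key, scale, target in (
                ("mu", s_mu, 0.35), ("f", s_f, 0.25), ("F", s_F, 0.35),
                ("M", s_M, 0.35),
            ):
                rate = acc[key] / adapt_interval
                scale *= np.exp(np.clip(rate - target, -0.5, 0.5))
                np.clip(scale, 1e-3, 50.0, out=scale)
                acc[key][...] = 0.0

        if step >= keep_from and (step - keep_from + 1) % config.thin == 0:
            store["mu"][chain, out_idx] = mu
            store["sigma"][chain, out_idx] = sigma
            store["f"][chain, out_idx] = f
            store["FWL"][chain, out_idx] = FWL
            store["MTS"][chain, out_idx] = MTS
            out_idx += 1


def log_posterior(point: Mapping[str, np.ndarray], model: OMSModel) -> float:
    """Module-level convenience wrapper around :meth:`OMSModel.log_posterior`."""
    return model.log_posterior(point)
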