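# Methods

## The model

`omsm` estimates, per consumer sample *k*, the fractional contributions
f*ᵢₖ* of candidate basal organic-matter sources and the trophic structure —
total food-web length (FWL), metazoan trophic steps (MTS), and protozoan
trophic steps (PTS = FWL − MTS) — from amino-acid δ¹⁵N values, all in a
single joint posterior.

The directed graph, in sampling notation:

```
X[j,i,r] ~ Normal(mu[j,i], sigma[j,i])          source replicates
mu[j,i]  ~ Uniform(-100, 100)                    (informative normal optional)
1/sigma[j,i]^2 ~ Gamma(0.001, 0.001)             (or gamma on sigma, by flag)

f[k]     ~ Dirichlet(alpha)                      alpha = (1,...,1) by default
base[j,k]    = sum_i f[i,k] * mu[j,i]            linear delta-space mixing

mF[k] = (Y[fwl,k] - base[fwl,k]) / D_fwl         ratio estimator, FWL tracer
sF[k] = |mF[k]| * sqrt((a[fwl,k]/Y[fwl,k])^2 + (sd(D_fwl)/D_fwl)^2)
FWL[k]   ~ Normal(mF[k], sF[k])                  (MTS analogous via its tracer)
PTS[k]   = FWL[k] - MTS[k]

Y[j,k]   ~ Normal(base[j,k] + PTS*Dp[j] + MTS*Dm[j], s[j,k])   mixing tracers
```

with the class reductions: a *conservative* tracer has Dp = Dm = 0 and
s[j,k] = the analytical SD α; a *constant* tracer has Dp ≡ Dm and
s[j,k] = sqrt(α² + (FWL·sd(Dm))²); a *variable* tracer keeps both terms,
s[j,k] = sqrt(α² + (PTS·sd(Dp))² + (MTS·sd(Dm))²).  The constant-class
uncertainty is *not* the variable-class formula with equal SDs — the
quadrature differs (FWL² vs PTS² + MTS²) — and the two code paths are kept
distinct and tested against each other.

Key assumptions: linear mixing in δ-units (no concentration weighting);
normal within-source variability; trophic discrimination accumulates
additively per step with normally distributed uncertainty; mixing and
trophic tracer sets are disjoint; at least n_sources + 1 independent
tracers are needed to fully constrain the system.

The trophic-parameter SDs use the *printed* relative-error form: the
consumer δ value enters through σ(δ)/δ, i.e. relative to its absolute
position on the δ scale, not to the consumer-minus-base difference.  This
is implemented verbatim; `trophic_uncertainty` warns when |δ| < 1 ‰, where
the ratio becomes unstable, and the Monte-Carlo comparison in the test
suite quantifies how far the first-order form sits from a full nonlinear
simulation (2–4% when every relative uncertainty is ≤ 0.1; the divergence
grows as ~3(σ/Δ)² beyond that).

## Default tracers and discrimination factors

The registry ships per-step Δ¹⁵N values (‰) for twelve amino acids,
compiled from controlled feeding studies on ammonia-excreting aquatic
consumers at trophic position ≤ 3, with protozoan and metazoan experiments
aggregated separately for amino acids whose discrimination differs
significantly between the two groups (Welch test, p < 0.05):

| class | tracers | defaults |
|---|---|---|
| constant | Ala 6.3±2.6, Pro 5.8±1.7, Gly 2.9±3.1, Ser 2.6±3.2, Phe 0.3±0.5, Lys 1.2±1.2 | all-experiment means |
| variable | Glx 8±1.7 / 0.5±1.0, Asx 5.7±1.9 / 0.8±1.4, Leu 5.6±2.4 / 1.4±0.6, Thr −5.9±1.5 / −2±0.6 | metazoan / protozoan means |
| excluded | Ile 4.6±3.2, Val 3.9±2.8 | marginal group differences (0.05 < p < 0.1) |

Threonine's metazoan value is the regression-based estimate (δ¹⁵N_Thr−Phe
on δ¹⁵N_Glx−Phe in wild plankton), which agrees with the feeding-study mean
but is better constrained.  The default configuration uses Pro for FWL
(lowest relative TDF uncertainty among constant tracers, 0.29), Glx for MTS
(lowest among variable tracers, 0.21), and Phe/Lys/Thr as mixing tracers;
Phe is treated as conservative by default (`treat_phe_conservative`),
since its 0.3 ± 0.5 ‰ per-step factor is negligible in short food webs and
dropping it removes an uncertainty term.  The `nonfractionating_variant`
flag reproduces the simplified comparison model (Thr excluded, Phe and Lys
conservative) used to show why modelling discrimination matters.

## Sampler

A seeded, adaptive Metropolis-within-Gibbs kernel written for this model
(no external probabilistic-programming engine):

- source precisions: exact conjugate gamma Gibbs draws (under the default
  precision-gamma prior; a log-scale Metropolis step under the σ-gamma
  flag);
- source means: per-tracer Gaussian random-walk Metropolis — their full
  conditionals factorise across tracers, so one vectorised accept/reject
  per source group updates all tracers at once;
- mixing vectors: symmetric random walk in additive-log-ratio space with
  the simplex Jacobian (Σ log fᵢ) in the target, one scalar proposal scale
  per consumer;
- FWL and MTS: scalar random walks, vectorised across consumers (consumers
  are conditionally independent given the source parameters).

Proposal scales adapt toward target acceptance rates (0.35 scalar, 0.25 simplex)
during the adaptation phase only; afterwards the kernel is fixed, so the
retained chain is a valid Markov chain.  Default run lengths: 3 chains ×
(5,000 adapt + 10,000 burn-in + 10,000 sampling, thin 10), giving 3,000
retained draws.  Initialisation is at plug-in
values — empirical source statistics, the simplex centroid, ratio-estimator
FWL/MTS — with a small per-chain jitter.

Convergence is assessed by split-R̂ < 1.05 and bulk ESS > 200 per parameter
(via `arviz`); failures are attached to the draws object and raised as a
warning, never silently ignored.  Correctness is verified three independent
ways in the test suite: a dense-grid numerical posterior on a two-source
toy (agreement of posterior means to < 0.01 against a 0.05 tolerance),
closed-form normal posteriors for source means under large replication, and
prior-only runs recovering the uniform-Dirichlet marginals.

Numerical choices: the propagated trophic SDs are floored at 1e−9 inside
density evaluations (the printed formulas give exactly zero SD when the
ratio estimator is zero); simplex draws are clipped at 1e−300 before logs;
FWL/MTS normals are untruncated by default, with a `truncate_at_zero` flag
restricting FWL, MTS and PTS to non-negative values (implemented as a
support constraint).  Fixed seeds make runs bit-reproducible; every CLI run
writes a manifest with input hashes, configuration, seed and version.

`build_model(..., fix_source_params=True)` pins source means/SDs at their
sample statistics instead of sampling them — the MixSIAR-style "fixed
source" simplification — which is also what makes low-dimensional grid
comparisons exact.  `prior_only=True` drops the mixing likelihood, leaving
the prior plus trophic-latent structure (under which the f-marginal is
provably still Dirichlet, a property the tests exercise).

## Posterior summaries

HDIs are shortest contiguous sample windows: among all windows of
⌈level·n⌉ sorted draws, the narrowest (earliest on ties, so plateaus are
deterministic).  `summarize` computes the four levels (50/75/90/95%) nested
by construction — the 95% window is unconstrained, and each lower level
takes the shortest window *inside* the next higher interval.  For unimodal
draws this coincides with independent shortest windows; for multimodal or
plateaued draw sets (which can otherwise produce non-nested independent
windows) it resolves the ambiguity deterministically.  Draws are pooled
across chains before summarisation.

The mode is the argmax of a Gaussian KDE (Silverman bandwidth) on a
512-point grid over the draw range; mixing coefficients are estimated on
the logit scale and back-transformed (with the Jacobian) to avoid boundary
bias near 0 and 1.

## Synthetic data

The simulator provides a self-contained mesopelagic-style validation
design with no external data dependencies:

- **Sources**: three groups × five replicates, Normal(group mean, 1 ‰) per
  tracer.  The default geometry mimics the observed particle structure —
  Phe and Lys order the groups along one axis (surface 0/1 ‰ < large
  4/5 ‰ < small 8/9 ‰), while Thr forms a second, largely orthogonal axis
  on which large particles are uniquely low (−16 ‰ vs −8/−9 ‰); Pro and
  Glx (trophic tracers) track the Phe/Lys axis.  Between-group separations
  are ≥ 3 within-group SDs on the informative axes.  The 1 ‰ within-group
  SD reflects typical within-class variability of marine particle δ¹⁵N_AA
  values.
- **Consumers**: f ~ Dirichlet(1,1,1), PTS ~ U(0, 1), MTS ~ U(1, 2) (so
  FWL spans 1–3 trophic steps), with tracer values given exactly by the
  forward model at the empirical source means (noise_sd = 0 by default; a
  zero-noise round trip through the forward model is exact to 1e−12).  An
  analytical SD of 0.5 ‰ — a typical AA-CSIA measurement uncertainty — is
  attached to every simulated value for fitting.

What the simulator does *not* emulate: seasonal or depth structure within
source groups, non-normal within-group variability, correlated analytical
errors across amino acids, and real TDF misspecification (consumers are
generated with the same registry means the model fits with).  Passing
recovery tests therefore demonstrate internal consistency of model +
sampler + summaries under correctly specified conditions, not robustness
to the additional error sources present in field data.

## Validation studies and problem sizes

The packaged recovery study fits 20 simulated consumers on the three-source
panel with chains at one quarter of the default lengths (1,250 adapt /
2,500 burn-in / 2,500 sampling, thin 10, 3 chains) — sizes chosen so the
full study runs in about half a minute on one CPU while retaining 750
pooled draws per parameter.  On this study the 95% HDIs cover the true
mixing fractions in ≥ 85% of cases and the true trophic parameters in
≥ 90%, and the mean absolute mode discrepancy for mixing fractions stays
within 15 percentage points; `scripts/acceptance.py` recomputes these
quantities from scratch for any seed.

## Known limitations

- **Many consumers, few source replicates.**  Because the FWL/MTS latent
  SDs are proportional to their parameter-dependent means, each consumer
  contributes a 1/σ normalization factor that rewards configurations with
  shorter food webs.  With many consumers (≈ 50) sharing source groups
  measured by only ~5 replicates, this pull can drag the FWL-tracer source
  means away from the source data (the vague dispersion prior lets σ
  inflate) and bias food-web lengths low by as much as a full trophic
  step — an attractor of the model structure itself, not a sampler
  artefact (independent chains agree, and full-length runs reproduce it).
  Mitigations: more source replicates, informative priors on the trophic
  tracers' source means, or fitting consumers in smaller batches.  The
  packaged studies use 20 consumers, where recovery is accurate across
  seeds.
- Mixing is linear in δ-units; concentration-weighted mixing is out of
  scope.
- HDIs are single intervals; multimodal posteriors are summarised by their
  best single window, not by unions.
- Carbon isotope tracers (δ¹³C of essential amino acids) are not supported
  in this version, though the conservative-tracer class is the natural
  entry point for them.
- Protozoan discrimination factors rest on very few feeding experiments;
  the registry's proto SDs should be treated as optimistic.
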