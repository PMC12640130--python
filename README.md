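# omsm — organic-matter supply modelling for amino-acid δ¹⁵N data

`omsm` is a Bayesian mixing model for compound-specific nitrogen isotope
values of individual amino acids (AA-CSIA).  It is aimed at trophic
ecologists who need to trace basal organic-matter sources — for example
surface particles, large sinking particles, and small suspended particles in
a mesopelagic food web — through an *unknown* number of intervening trophic
steps to a consumer such as a zooplankter.

Classical isotope mixing models (MixSIAR, simmr) assume a single, known
trophic transfer between diet and consumer.  In planktonic food webs that
assumption fails twice over: consumers may sit several transfers above the
particle pool, and those transfers mix protozoan and metazoan steps, which
fractionate amino-acid nitrogen very differently.  Worse, the amount of
trophic discrimination depends on which sources are used — so the mixing
equations and the trophic equations must be solved *simultaneously*.  That
joint estimation is what this package implements.

## The model

For tracer *j* (the δ¹⁵N of one amino acid, ‰), source *i*, consumer *k*:

- **Sources.**  Replicate measurements X*ⱼᵢ* ~ Normal(μ*ⱼᵢ*, σ*ⱼᵢ*), with a
  flat prior on μ*ⱼᵢ* (±100 ‰) and a vague gamma prior on the precision.
- **Mixing.**  f*ₖ* ~ Dirichlet(1, …, 1) and the base of the food web is the
  linear mixture  μ*ⱼₖ*,base = Σ*ᵢ* f*ᵢₖ* μ*ⱼᵢ*.
- **Trophic structure.**  A constant-discrimination tracer (proline by
  default, Δ¹⁵N = 5.8 ± 1.7 ‰ per step) dates the whole food web:
  FWL*ₖ* ~ Normal((δ¹⁵N_Pro,*k* − μ_Pro,base)/Δ_Pro, σ_FWL).  A
  variable-discrimination tracer (glutamic acid, Δ_meta = 8 ± 1.7 ‰,
  Δ_proto = 0.5 ± 1 ‰) counts metazoan steps the same way, and protozoan
  steps are the difference PTS*ₖ* = FWL*ₖ* − MTS*ₖ*.
- **Consumers.**  Each mixing tracer (phenylalanine, lysine, threonine by
  default) contributes  Y*ⱼₖ* ~ Normal(μ*ⱼₖ*,base + PTS·Δ*ⱼ*,proto +
  MTS·Δ*ⱼ*,meta, σ*ⱼₖ*), with per-class reductions (conservative tracers add
  nothing; constant tracers add FWL·Δ*ⱼ*) and uncertainties combining
  analytical error with step-scaled Δ¹⁵N spread in quadrature.

Posteriors are explored by a seeded, adaptive Metropolis-within-Gibbs
sampler (3 chains; 5,000 adaptation, 10,000 burn-in, 10,000 sampling steps
thinned by 10, by default) and summarised by mean, kernel-density mode, and
50/75/90/95% highest-density intervals.  A source contribution is
established at 95% confidence when the 95% HDI excludes zero.

The default trophic-discrimination registry (per-step Δ¹⁵N for twelve amino
acids, metazoan and protozoan) ships with the package; `omsm.tdf` can
rebuild such a registry from a controlled-feeding-study compilation, test
protozoa-vs-metazoa differences, and derive regression-based Δ¹⁵N values
from Phe-normalised field data.  `omsm.diagnostics` quantifies whether a
candidate tracer panel actually spans enough independent axes to resolve
the sources (Pearson correlations, PCA variance, entropy-based effective
dimensionality).

## Worked example

```python
import omsm

# a three-source synthetic panel (surface / large / small particle
# analogues) and 20 consumers with known mixing + trophic parameters
sources = omsm.default_source_panel(seed=3)
consumers, truth = omsm.simulate_consumers(sources, n=20, seed=4)

model = omsm.build_model(sources, consumers, omsm.default_tdf_table())
draws = omsm.run_mcmc(model, omsm.MCMCConfig(
    chains=3, adapt=1250, burn_in=2500, samples=2500, thin=10, seed=1))
table = omsm.summarize(draws).set_index("parameter")
for name in ("f[sim006,surface]", "FWL[sim006]"):
    row = table.loc[name]
    print(f"{name}: mode={row['mode']:.2f} "
          f"95% HDI=({row['hdi95_lo']:.2f}, {row['hdi95_hi']:.2f})")
print("true f(surface):", round(truth.table.loc[5, "f(surface)"], 2),
      " true FWL:", round(truth.table.loc[5, "FWL"], 2))
```

prints

```
f[sim006,surface]: mode=0.31 95% HDI=(0.07, 0.63)
FWL[sim006]: mode=1.76 95% HDI=(0.84, 3.00)
true f(surface): 0.39  true FWL: 2.01
```

— the posterior mode tracks the generating surface-particle contribution,
the 95% interval excludes zero (so a surface contribution is established at
95% confidence for this sample), and the food-web-length posterior brackets
the true two-step structure.  Scoring all 20 consumers with
`omsm.validate.recovery_report` gives 95%-HDI coverage of 0.97 for the
mixing fractions and 1.00 for the trophic parameters on this study.

The same pipeline is available from the shell:

```bash
omsm simulate --n 20 --seed 1 --out study/
omsm fit --sources study/sources.csv --consumers study/consumers.csv \
         --out study/fit --seed 1
omsm validate --summary study/fit/summary.csv --truth study/truth.csv \
              --out study/recovery.json
omsm diagnose --sources study/sources.csv --tracers Phe,Lys,Thr
```

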