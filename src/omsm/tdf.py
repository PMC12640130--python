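"""Trophic-discrimination-factor estimation and tracer classification.

Two complementary routes to per-amino-acid Δ¹⁵N values are provided:

1. aggregation of controlled-feeding-study results, with Welch t-tests
   comparing protozoan vs metazoan experiments to classify each amino acid's
   discrimination behaviour (constant across step types, variable between
   them, or marginal — recommended for exclusion);
2. a regression route for field data, where Phe-normalised δ¹⁵N values are
   regressed on a trophic-position proxy (Glx−Phe or Ala−Phe) and the slope
   converted to a Δ¹⁵N value via the proxy tracer's own discrimination
   factor:  Δ¹⁵N_AA = m · TDF_ref + Δ¹⁵N_Phe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import OMSMWarning, canonical_aa

__all__ = [
    "FeedingExperiment",
    "FilterRule",
    "RegressionTDF",
    "aggregate_tdfs",
    "classify_tracer",
    "compare_groups",
    "default_compilation_filters",
    "filter_experiments",
    "read_feeding_compilation",
    "regression_tdf",
    "synthetic_feeding_compilation",
]


@dataclass(frozen=True)
class FeedingExperiment:
    """One controlled-feeding experiment: per-amino-acid Δ¹⁵N values (‰).

    Replicates are pooled before this record is formed, so the experiment is
    the unit of averaging.  ``group`` is ``"protozoa"`` or ``"metazoa"``;
    missing amino acids are simply absent from ``deltas``.  Optional
    ecological attributes (``trophic_position``, ``excretion``, ``habitat``,
    ``diet``) support declarative compilation filtering.
    """

    species: str
    group: str
    deltas: Mapping[str, float]
    replicates: int = 1
    trophic_position: float | None = None
    excretion: str | None = None
    habitat: str | None = None
    diet: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("protozoa", "metazoa"):
            raise ValueError(f"group must be protozoa|metazoa, got {self.group!r}")
        deltas = {canonical_aa(k): float(v) for k, v in dict(self.deltas).items()
                  if np.isfinite(v)}
        if not deltas:
            raise ValueError(f"experiment on {self.species!r} has no amino acids")
        object.__setattr__(self, "deltas", deltas)


@dataclass(frozen=True)
class FilterRule:
    """A named, logged predicate over experiments (True keeps the record)."""

    name: str
    keep: "callable"


def default_compilation_filters() -> list[FilterRule]:
    """The compilation inclusion criteria, as declarative rules: keep aquatic
    ammonia-excreting taxa with trophic position ≤ 3, and drop the one
    *Acanthopagrus butcheri* vegetable-meal experiment (anomalously high Δ)."""
    return [
        FilterRule(
            "aquatic ammonia excreters",
            lambda e: (e.excretion is None or e.excretion == "ammonia")
            and (e.habitat is None or e.habitat == "aquatic"),
        ),
        FilterRule(
            "trophic position <= 3",
            lambda e: e.trophic_position is None or e.trophic_position <= 3,
        ),
        FilterRule(
            "drop Acanthopagrus butcheri vegetable meal",
            lambda e: not (
                e.species == "Acanthopagrus butcheri"
                and (e.diet or "").lower().startswith("vegetable")
            ),
        ),
    ]


def filter_experiments(
    experiments: Sequence[FeedingExperiment],
    rules: Sequence[FilterRule] | None = None,
    log: list[str] | None = None,
) -> list[FeedingExperiment]:
    """Apply filter rules, recording per-rule exclusion counts in ``log``."""
    rules = list(rules) if rules is not None else default_compilation_filters()
    kept = list(experiments)
    for rule in rules:
        before = len(kept)
        kept = [e for e in kept if rule.keep(e)]
        if log is not None:
            log.append(f"filter {rule.name!r}: removed {before - len(kept)}, "
                       f"kept {len(kept)}")
    return kept


def aggregate_tdfs(
    experiments: Sequence[FeedingExperiment], subset: str = "all"
) -> pd.DataFrame:
    """Mean ± SD of Δ¹⁵N per amino acid over a subset of experiments.

    ``subset`` is ``all``, ``metazoa`` or ``protozoa``.  Experiments missing
    an amino acid are skipped for that amino acid; amino acids observed in
    fewer than two experiments of the subset are omitted with a warning.
    Returns a DataFrame indexed by amino acid with columns ``mean``, ``sd``,
    ``n``.
    """
    if subset not in ("all", "metazoa", "protozoa"):
        raise ValueError(f"subset must be all|metazoa|protozoa, got {subset!r}")
    pool = [e for e in experiments if subset == "all" or e.group == subset]
    if not pool:
        raise ValueError(f"no experiments in subset {subset!r}")
    by_aa: dict[str, list[float]] = {}
    for e in pool:
        for aa, v in e.deltas.items():
            by_aa.setdefault(aa, []).append(v)
    rows = {}
    for aa, vals in sorted(by_aa.items()):
        if len(vals) < 2:
            warnings.warn(
                f"amino acid {aa}: only {len(vals)} experiment(s) in subset "
                f"{subset!r}; omitted from aggregation",
                OMSMWarning, stacklevel=2,
            )
            continue
        arr = np.asarray(vals, float)
        rows[aa] = {"mean": arr.mean(), "sd": arr.std(ddof=1), "n": len(vals)}
    return pd.DataFrame(rows).T.rename_axis("aa")


def compare_groups(
    experiments: Sequence[FeedingExperiment], amino_acid: str
) -> float:
    """Welch (heteroskedastic, two-tailed) t-test p-value comparing protozoan
    vs metazoan Δ¹⁵N values for one amino acid across experiments."""
    aa = canonical_aa(amino_acid)
    meta = [e.deltas[aa] for e in experiments
            if e.group == "metazoa" and aa in e.deltas]
    proto = [e.deltas[aa] for e in experiments
             if e.group == "protozoa" and aa in e.deltas]
    if len(meta) < 2 or len(proto) < 2:
        raise ValueError(
            f"{aa}: need >= 2 experiments per group "
            f"(metazoa={len(meta)}, protozoa={len(proto)})"
        )
    res = stats.ttest_ind(proto, meta, equal_var=False)
    return float(res.pvalue)


def classify_tracer(
    p_value: float, thresholds: tuple[float, float] = (0.05, 0.1)
) -> str:
    """Discrimination class from the protozoa-vs-metazoa test p-value.

    p < 0.05 → ``variable`` (step types fractionate differently);
    p > 0.1 → ``constant``; in between → ``marginal`` (difference too
    uncertain to parameterise — exclusion from the model is recommended).
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    lo, hi = thresholds
    if p_value < lo:
        return "variable"
    if p_value > hi:
        return "constant"
    return "marginal"


@dataclass(frozen=True)
class RegressionTDF:
    """A regression-derived Δ¹⁵N estimate and its provenance.

    ``delta = slope * tdf_ref + delta_phe`` with the uncertainty combining
    the slope standard error, the reference tracer's Δ SD and Phe's Δ SD in
    first-order quadrature.
    """

    amino_acid: str
    reference: str
    slope: float
    slope_se: float
    delta: float
    sd: float
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    n_obs: int


def regression_tdf(
    data: pd.DataFrame,
    amino_acid: str,
    reference: str,
    tdf_ref: float,
    delta_phe: float,
    *,
    sigma_tdf_ref: float = 0.0,
    sigma_delta_phe: float = 0.0,
) -> RegressionTDF:
    """Estimate Δ¹⁵N for one amino acid by regression on a trophic proxy.

    ``data`` holds Phe-normalised δ¹⁵N values: a column per amino acid named
    ``<AA>`` (already δ¹⁵N_AA − δ¹⁵N_Phe, ‰) and a ``location`` column.  The
    response ``amino_acid`` is regressed by OLS on the ``reference`` column
    (Glx or Ala, also Phe-normalised) with location as an additive,
    non-interacting categorical predictor.  The slope ``m`` is converted to
    a discrimination factor via ``Δ = m * tdf_ref + delta_phe``, where
    ``tdf_ref`` is the reference amino acid's Δ¹⁵N relative to Phe.

    Uncertainty: ``sd² = (tdf_ref·SE_m)² + (m·σ(tdf_ref))² + σ(Δ_Phe)²``
    (first-order propagation treating the three inputs as independent).
    """
    import statsmodels.formula.api as smf

    aa = canonical_aa(amino_acid)
    ref = canonical_aa(reference)
    if ref not in ("Glx", "Ala"):
        raise ValueError(f"reference must be Glx or Ala, got {reference!r}")
    cols = [aa, ref]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data lacks column(s) {missing}")
    df = data.rename(columns={aa: "_y", ref: "_x"}).copy()
    if len(df) < 10:
        raise ValueError(f"need >= 10 observations, got {len(df)}")
    formula = "_y ~ _x + C(location)" if "location" in df.columns and \
        df["location"].nunique() > 1 else "_y ~ _x"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    m = float(fit.params["_x"])
    se = float(fit.bse["_x"])
    delta = m * tdf_ref + delta_phe
    sd = float(np.sqrt((tdf_ref * se) ** 2 + (m * sigma_tdf_ref) ** 2
                       + sigma_delta_phe**2))
    return RegressionTDF(
        amino_acid=aa,
        reference=ref,
        slope=m,
        slope_se=se,
        delta=float(delta),
        sd=sd,
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
    )


def read_feeding_compilation(path_or_buf) -> list[FeedingExperiment]:
    """Read a feeding-study CSV: columns ``species``, ``group``,
    ``replicates`` (optional), ``diet``/``excretion``/``habitat``/
    ``trophic_position`` (optional), plus one Δ¹⁵N column per amino acid."""
    df = pd.read_csv(path_or_buf)
    meta_cols = {"species", "group", "replicates", "diet", "excretion",
                 "habitat", "trophic_position"}
    aa_cols = [c for c in df.columns if c not in meta_cols]
    out = []
    for _, row in df.iterrows():
        deltas = {c: row[c] for c in aa_cols if pd.notna(row[c])}
        out.append(FeedingExperiment(
            species=str(row["species"]),
            group=str(row["group"]),
            deltas=deltas,
            replicates=int(row.get("replicates", 1) or 1),
            trophic_position=(float(row["trophic_position"])
                              if "trophic_position" in df.columns
                              and pd.notna(row["trophic_position"]) else None),
            excretion=(str(row["excretion"]) if "excretion" in df.columns
                       and pd.notna(row["excretion"]) else None),
            habitat=(str(row["habitat"]) if "habitat" in df.columns
                     and pd.notna(row["habitat"]) else None),
            diet=(str(row["diet"]) if "diet" in df.columns
                  and pd.notna(row["diet"]) else None),
        ))
    return out


def synthetic_feeding_compilation(
    seed: int = 0,
    n_metazoa: int = 18,
    n_protozoa: int = 3,
    tdf_table=None,
) -> list[FeedingExperiment]:
    """A synthetic stand-in for a feeding-study compilation (clearly labelled
    as such): experiments are drawn around the default registry's Δ values
    with the registry's between-experiment SDs, for testing the aggregation
    and classification machinery without redistributing published data."""
    from .core import default_tdf_table

    tdf = tdf_table if tdf_table is not None else default_tdf_table()
    rng = np.random.default_rng(seed)
    out = []
    for g, n in (("metazoa", n_metazoa), ("protozoa", n_protozoa)):
        for idx in range(n):
            deltas = {}
            for aa in tdf:
                dm, sdm, dp, sdp = tdf.values(aa)
                centre, spread = (dm, sdm) if g == "metazoa" else (dp, sdp)
                deltas[aa] = rng.normal(centre, max(spread, 0.1))
            out.append(FeedingExperiment(
                species=f"synthetic {g} {idx}", group=g, deltas=deltas,
                replicates=3, trophic_position=2.0, excretion="ammonia",
                habitat="aquatic", diet="control",
            ))
    return out
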