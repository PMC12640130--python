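"""Posterior-vs-truth assessment for simulation studies.

Given posterior summaries for a set of simulated consumers and the recorded
generating truths, this module counts HDI coverage at each credibility
level, computes mode-vs-truth discrepancy statistics, and fits recovery
regressions (modelled value on truth, and discrepancy on truth) to expose
systematic bias.  Mixing coefficients, being compositional, use a
quasibinomial GLM with a logit link; trophic parameters use ordinary least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .summary import HDI_LEVELS

__all__ = [
    "RecoveryReport",
    "coverage_counts",
    "discrepancy_stats",
    "plot_recovery",
    "recovery_regression",
    "recovery_report",
]


def coverage_counts(
    summaries: pd.DataFrame,
    truths: Mapping[str, float],
    levels: Sequence[float] = HDI_LEVELS,
) -> dict[float, int]:
    """Count truths lying inside the HDI at each level (closed intervals).

    ``summaries`` is a summary table (one row per parameter with
    ``hdi<pct>_lo/_hi`` columns); ``truths`` maps parameter name -> true
    value.  Every truth must have a summary row.
    """
    idx = summaries.set_index("parameter")
    missing = [p for p in truths if p not in idx.index]
    if missing:
        raise KeyError(f"no summary for parameter(s) {missing}")
    counts = {}
    for lv in levels:
        pct = int(round(lv * 100))
        lo = idx[f"hdi{pct}_lo"]
        hi = idx[f"hdi{pct}_hi"]
        c = 0
        for p, t in truths.items():
            if lo[p] <= t <= hi[p]:  # endpoint counts as covered
                c += 1
        counts[lv] = c
    return counts


def discrepancy_stats(
    modes: Sequence[float], truths: Sequence[float], as_percent: bool = False
) -> tuple[float, float]:
    """Mean and max absolute discrepancy |mode − truth|.

    ``as_percent=True`` reports in percentage points (for mixing fractions).
    """
    m = np.asarray(modes, float)
    t = np.asarray(truths, float)
    if m.size == 0 or m.shape != t.shape:
        raise ValueError("modes and truths must be equal-length, non-empty")
    d = np.abs(m - t)
    scale = 100.0 if as_percent else 1.0
    return float(d.mean() * scale), float(d.max() * scale)


def recovery_regression(
    modes: Sequence[float], truths: Sequence[float], compositional: bool = False
) -> dict[str, object]:
    """Fit modelled-value-on-truth and discrepancy-on-truth regressions.

    Linear OLS by default; for compositional responses (mixing fractions) the
    value regression uses a quasibinomial GLM with a logit link (binomial
    family, Pearson-χ² dispersion), whose fitted curve respects the (0, 1)
    range.  Returns slope/intercept with 95% CIs for the value fit (linear
    case) or coefficient table (GLM case), plus the OLS discrepancy fit.
    """
    import statsmodels.api as sm

    m = np.asarray(modes, float)
    t = np.asarray(truths, float)
    if m.size < 5:
        raise ValueError("need at least 5 (mode, truth) pairs")
    if np.ptp(t) == 0:
        raise ValueError("degenerate truth variance")
    X = sm.add_constant(t)

    out: dict[str, object] = {"compositional": bool(compositional)}
    if compositional:
        glm = sm.GLM(np.clip(m, 1e-9, 1 - 1e-9), X,
                     family=sm.families.Binomial())
        fit = glm.fit(scale="X2")  # quasibinomial: Pearson-chi2 dispersion
        out["value_fit"] = {
            "intercept": float(fit.params[0]),
            "slope": float(fit.params[1]),
            "intercept_ci": tuple(map(float, fit.conf_int()[0])),
            "slope_ci": tuple(map(float, fit.conf_int()[1])),
            "scale": float(fit.scale),
            "link": "logit",
        }
    else:
        fit = sm.OLS(m, X).fit()
        ci = fit.conf_int()
        out["value_fit"] = {
            "intercept": float(fit.params[0]),
            "slope": float(fit.params[1]),
            "intercept_ci": (float(ci[0][0]), float(ci[0][1])),
            "slope_ci": (float(ci[1][0]), float(ci[1][1])),
            "r_squared": float(fit.rsquared),
        }
    dfit = sm.OLS(m - t, X).fit()
    dci = dfit.conf_int()
    out["discrepancy_fit"] = {
        "intercept": float(dfit.params[0]),
        "slope": float(dfit.params[1]),
        "intercept_ci": (float(dci[0][0]), float(dci[0][1])),
        "slope_ci": (float(dci[1][0]), float(dci[1][1])),
    }
    return out


@dataclass
class RecoveryReport:
    """Recovery assessment for one parameter family (e.g. f(surface), PTS).

    ``coverage`` maps HDI level -> count of samples whose truth the interval
    covered (monotone non-decreasing in the level, since HDIs nest);
    ``n`` is the number of samples scored.
    """

    family: str
    n: int
    coverage: dict[float, int]
    mean_abs_discrepancy: float
    max_abs_discrepancy: float
    regression: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = sorted(self.coverage)
        counts = [self.coverage[lv] for lv in levels]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError(
                f"{self.family}: coverage counts must be non-decreasing "
                f"with HDI level, got {self.coverage}"
            )
        if self.mean_abs_discrepancy < 0 or self.max_abs_discrepancy < 0:
            raise ValueError("absolute discrepancies must be >= 0")

    def coverage_rate(self, level: float) -> float:
        return self.coverage[level] / self.n


def recovery_report(
    summaries: pd.DataFrame,
    truth,
    levels: Sequence[float] = HDI_LEVELS,
) -> dict[str, RecoveryReport]:
    """Score a fit of simulated consumers against its recorded truths.

    ``truth`` is a :class:`~omsm.simulate.SimulationTruth`; parameter names
    in ``summaries`` must follow the sampler's naming (``f[<id>,<group>]``,
    ``PTS[<id>]``, ``MTS[<id>]``, ``FWL[<id>]``).  Returns one report per
    family: each mixing component and each trophic parameter (mixing
    discrepancies in percentage points).
    """
    tbl = truth.table
    ids = list(tbl["sample_id"])
    reports: dict[str, RecoveryReport] = {}
    modes = summaries.set_index("parameter")["mode"]

    def build(family: str, names: list[str], true_vals: np.ndarray,
              compositional: bool) -> RecoveryReport:
        truths_map = dict(zip(names, true_vals))
        cov = coverage_counts(summaries, truths_map, levels)
        mvals = modes[names].to_numpy(float)
        mean_d, max_d = discrepancy_stats(
            mvals, true_vals, as_percent=compositional
        )
        reg = (recovery_regression(mvals, true_vals, compositional)
               if len(names) >= 5 and np.ptp(true_vals) > 0 else {})
        return RecoveryReport(
            family=family, n=len(names), coverage=cov,
            mean_abs_discrepancy=mean_d, max_abs_discrepancy=max_d,
            regression=reg,
        )

    for g in truth.groups:
        names = [f"f[{cid},{g}]" for cid in ids]
        reports[f"f({g})"] = build(
            f"f({g})", names, tbl[f"f({g})"].to_numpy(float), True
        )
    for fam in ("PTS", "MTS", "FWL"):
        names = [f"{fam}[{cid}]" for cid in ids]
        reports[fam] = build(fam, names, tbl[fam].to_numpy(float), False)
    return reports


def plot_recovery(
    summaries: pd.DataFrame,
    truth,
    family: str,
    ax=None,
):
    """Truth-vs-mode scatter with 95% HDI whiskers for one parameter family.

    ``family`` is ``f(<group>)``, ``PTS``, ``MTS`` or ``FWL``.  Returns the
    matplotlib axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tbl = truth.table
    ids = list(tbl["sample_id"])
    if family.startswith("f("):
        g = family[2:-1]
        names = [f"f[{cid},{g}]" for cid in ids]
        true_vals = tbl[family].to_numpy(float)
    else:
        names = [f"{family}[{cid}]" for cid in ids]
        true_vals = tbl[family].to_numpy(float)
    idx = summaries.set_index("parameter")
    mode = idx.loc[names, "mode"].to_numpy(float)
    lo = idx.loc[names, "hdi95_lo"].to_numpy(float)
    hi = idx.loc[names, "hdi95_hi"].to_numpy(float)

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.errorbar(true_vals, mode, yerr=[mode - lo, hi - mode], fmt="o",
                ms=4, lw=0.8, capsize=2, alpha=0.8)
    span = [min(true_vals.min(), lo.min()), max(true_vals.max(), hi.max())]
    ax.plot(span, span, color="goldenrod", lw=1, label="1:1")
    ax.set_xlabel(f"true {family}")
    ax.set_ylabel(f"posterior mode (95% HDI)")
    ax.set_title(family)
    ax.legend(frameon=False)
    return ax
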