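"""Posterior summarisation: means, KDE modes, highest-density intervals, and
the HDI-based hypothesis-testing helpers.

The HDI at level p is the shortest contiguous interval containing a fraction
p of the posterior draws — the model's statement of the minimum and maximum
plausible value of a parameter at that confidence.  A source contribution is
"established" at 95% confidence when the 95% HDI excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import gaussian_kde

__all__ = [
    "HDI_LEVELS",
    "PosteriorSummary",
    "hdi",
    "hdi_excludes",
    "nested_hdis",
    "posterior_mode",
    "summarize",
]

HDI_LEVELS = (0.50, 0.75, 0.90, 0.95)
_MIN_DRAWS = 100


def hdi(draws: Sequence[float], level: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(level * n)`` sorted draws.

    Ties on width are broken by taking the earliest (lowest) window, so the
    result is deterministic even for plateaus (e.g. uniform draws).
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < _MIN_DRAWS:
        raise ValueError(f"need at least {_MIN_DRAWS} draws for an HDI, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    m = math.ceil(level * n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: earliest window
    return float(x[i]), float(x[i + m - 1])


def nested_hdis(
    draws: Sequence[float], levels: Sequence[float] = HDI_LEVELS
) -> dict[float, tuple[float, float]]:
    """Shortest-window HDIs at several levels, nested by construction.

    The highest level uses the unconstrained shortest window; each lower
    level then takes the shortest window lying inside the next higher
    interval.  For well-behaved unimodal draws this coincides with
    independent :func:`hdi` calls; for plateaus or multimodal draw sets it
    resolves the (otherwise possible) non-nesting deterministically.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < _MIN_DRAWS:
        raise ValueError(f"need at least {_MIN_DRAWS} draws for an HDI, got {n}")
    out: dict[float, tuple[float, float]] = {}
    a, b = 0, n - 1  # allowed index range, inclusive
    for level in sorted(levels, reverse=True):
        if not 0.0 < level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {level}")
        m = math.ceil(level * n)
        starts = np.arange(a, b - m + 2)
        widths = x[starts + m - 1] - x[starts]
        i = int(starts[np.argmin(widths)])
        out[level] = (float(x[i]), float(x[i + m - 1]))
        a, b = i, i + m - 1
    return dict(sorted(out.items()))


def posterior_mode(
    draws: Sequence[float], *, bounded01: bool = False, grid_size: int = 512
) -> float:
    """Mode of a kernel density estimate over the draws.

    Gaussian KDE with Silverman bandwidth, maximised on a ``grid_size``-point
    grid spanning the draw range.  Parameters bounded on (0, 1) (mixing
    coefficients) are estimated on the logit scale and back-transformed,
    which avoids boundary bias of the unbounded KDE.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < _MIN_DRAWS:
        raise ValueError(
            f"need at least {_MIN_DRAWS} draws for a mode estimate, got {x.size}"
        )
    if np.ptp(x) == 0:
        return float(x[0])
    if bounded01:
        eps = 1e-6
        xc = np.clip(x, eps, 1 - eps)
        z = logit(xc)
        kde = gaussian_kde(z, bw_method="silverman")
        lo, hi = float(np.min(xc)), float(np.max(xc))
        grid = np.linspace(lo, hi, grid_size)
        grid = np.clip(grid, eps, 1 - eps)
        # density of f: p_z(logit(f)) / (f (1-f))
        dens = kde(logit(grid)) / (grid * (1.0 - grid))
        return float(grid[np.argmax(dens)])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(float(np.min(x)), float(np.max(x)), grid_size)
    return float(grid[np.argmax(kde(grid))])


def hdi_excludes(draws: Sequence[float], value: float, level: float) -> bool:
    """True iff ``value`` lies strictly outside the HDI at ``level``.

    The interval is treated as closed: a value exactly at an endpoint is
    considered covered (returns False).
    """
    lo, hi = hdi(draws, level)
    return bool(value < lo or value > hi)


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of one parameter's posterior: mean, KDE mode, nested HDIs."""

    parameter: str
    mean: float
    mode: float
    hdi: Mapping[float, tuple[float, float]]
    rhat: float = float("nan")
    ess: float = float("nan")
    flagged: bool = False

    def __post_init__(self) -> None:
        levels = sorted(self.hdi)
        for a, b in zip(levels, levels[1:]):
            lo_a, hi_a = self.hdi[a]
            lo_b, hi_b = self.hdi[b]
            if lo_a < lo_b - 1e-9 or hi_a > hi_b + 1e-9:
                raise ValueError(
                    f"{self.parameter}: HDI nesting violated between levels "
                    f"{a} and {b}"
                )


def _is_fraction_param(name: str) -> bool:
    return name.startswith("f[")


def summarize(
    draws,
    levels: Sequence[float] = HDI_LEVELS,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Summary table over a :class:`~omsm.inference.PosteriorDraws` object or
    a mapping of parameter name -> pooled draw vector.

    One row per parameter: mean, mode, HDI bounds at each level, and (when
    available) split-R̂ / ESS with a ``flagged`` convergence column.  Draws
    are pooled across chains before summarisation.  Mixing-coefficient
    parameters (names ``f[...]``) use the bounded-mode estimator.
    """
    if hasattr(draws, "arrays"):
        items = {name: draws.draws(name) for name in draws.parameters}
        rhat = dict(getattr(draws, "rhat", {}))
        ess = dict(getattr(draws, "ess", {}))
        flagged = set(getattr(draws, "flagged", []))
    else:
        items = {k: np.asarray(v, float).reshape(-1) for k, v in dict(draws).items()}
        rhat, ess, flagged = {}, {}, set()
    if parameters is not None:
        items = {k: items[k] for k in parameters}

    rows = []
    for name, x in items.items():
        row: dict[str, object] = {
            "parameter": name,
            "mean": float(np.mean(x)),
            "mode": posterior_mode(x, bounded01=_is_fraction_param(name)),
        }
        intervals = nested_hdis(x, levels)
        for lv, (lo, hi) in intervals.items():
            pct = int(round(lv * 100))
            row[f"hdi{pct}_lo"] = lo
            row[f"hdi{pct}_hi"] = hi
        # the nesting invariant is asserted by the summary record itself
        PosteriorSummary(
            parameter=name, mean=row["mean"], mode=row["mode"], hdi=intervals,
            rhat=rhat.get(name, float("nan")), ess=ess.get(name, float("nan")),
            flagged=name in flagged,
        )
        row["rhat"] = rhat.get(name, float("nan"))
        row["ess"] = ess.get(name, float("nan"))
        row["flagged"] = name in flagged
        rows.append(row)
    return pd.DataFrame(rows)
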