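"""Tracer-selection diagnostics: correlation structure, PCA variance
decomposition, and effective dimensionality of a tracer panel.

Mixing tracers should jointly separate the candidate sources while adding
independent information; since amino-acid δ¹⁵N values are often strongly
collinear, these diagnostics quantify how many effective axes a candidate
panel actually spans (for n sources, at least n − 1 independent tracers are
needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TracerPanel",
    "correlation_matrix",
    "effective_dimensionality",
    "pca_variance",
    "diagnostics_report",
]


@dataclass
class TracerPanel:
    """A samples × tracers matrix of δ¹⁵N values (‰) with group labels."""

    values: pd.DataFrame
    groups: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 3:
            raise ValueError("panel needs at least 3 samples")
        if self.values.isna().any().any():
            raise ValueError("panel contains missing cells")
        if self.groups is not None and len(self.groups) != len(self.values):
            raise ValueError("one group label per sample required")

    @classmethod
    def from_source_dataset(cls, sources, tracers=None) -> "TracerPanel":
        frames, labels = [], []
        for g in sources.groups:
            df = sources.samples[g]
            if tracers is not None:
                df = df[list(tracers)]
            frames.append(df)
            labels.extend([g] * len(df))
        return cls(pd.concat(frames, ignore_index=True), labels)


def _as_matrix(panel) -> np.ndarray:
    if isinstance(panel, TracerPanel):
        return panel.values.to_numpy(dtype=float)
    if isinstance(panel, pd.DataFrame):
        return panel.to_numpy(dtype=float)
    return np.asarray(panel, dtype=float)


def correlation_matrix(panel) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlations between tracers.

    Returns the symmetric correlation matrix and the mean absolute
    off-diagonal correlation (a one-number collinearity summary).  A
    zero-variance tracer is an error.
    """
    x = _as_matrix(panel)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0)
        raise ValueError(f"zero-variance tracer column(s): {bad.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    names = (list(panel.values.columns) if isinstance(panel, TracerPanel)
             else list(panel.columns) if isinstance(panel, pd.DataFrame)
             else list(range(x.shape[1])))
    off = r[~np.eye(r.shape[0], dtype=bool)]
    return pd.DataFrame(r, index=names, columns=names), float(np.mean(np.abs(off)))


def pca_variance(panel, scale: bool = False) -> np.ndarray:
    """Fractions of variance per principal component (non-increasing, sum 1).

    Computed from the covariance matrix of the raw (unscaled) values by
    default, matching the convention of analysing unscaled δ¹⁵N data;
    ``scale=True`` uses the correlation matrix instead.
    """
    x = _as_matrix(panel)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 tracers")
    if scale:
        sds = x.std(axis=0, ddof=1)
        if np.any(sds == 0):
            raise ValueError("zero-variance tracer; cannot scale")
        x = (x - x.mean(axis=0)) / sds
    cov = np.cov(x, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("degenerate covariance matrix (zero total variance)")
    return eig / total


def effective_dimensionality(panel) -> float:
    """Shannon-entropy effective dimensionality of the tracer covariance.

    ``exp(−Σ p_i ln p_i)`` over the normalised covariance eigenvalues p_i
    (the n1 estimator of the entropy-based dimensionality framework): equals
    the number of tracers for an isotropic cloud and 1 for rank-1 data.
    Invariant under orthogonal rotation of the panel.
    """
    p = pca_variance(panel)
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()))


def diagnostics_report(panel) -> dict[str, object]:
    """Bundle of the three diagnostics for a panel (plus a text rendering)."""
    corr, mean_abs_r = correlation_matrix(panel)
    var = pca_variance(panel)
    ed = effective_dimensionality(panel)
    lines = [
        f"tracers: {list(corr.columns)}",
        f"mean |r| (off-diagonal): {mean_abs_r:.3f}",
        "PCA variance fractions: "
        + ", ".join(f"PC{i + 1}={v:.3f}" for i, v in enumerate(var)),
        f"effective dimensionality: {ed:.2f}",
    ]
    return {
        "correlation": corr,
        "mean_abs_r": mean_abs_r,
        "pca_variance": var,
        "effective_dimensionality": ed,
        "text": "\n".join(lines),
    }
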