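"""File readers/writers, run configuration, and the run manifest.

The on-disk formats are wide CSVs mirroring typical AA-CSIA data layouts:
one row per sample, one column per amino acid (‰).  A long-format converter
is provided for draws and for users who prefer tidy tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConsumerSample,
    ModelConfig,
    SourceDataset,
    TDFTable,
    canonical_aa,
    default_model_config,
)
from .inference import MCMCConfig, PosteriorDraws, PriorConfig

__all__ = [
    "RunManifest",
    "draws_from_csv",
    "load_run_config",
    "read_consumers",
    "read_sources",
    "wide_to_long",
    "write_consumers",
    "write_sources",
]

# consumer-file columns that carry simulation truth rather than measurements
_TRUTH_COLS = {"PTS", "MTS", "FWL"}


def _canonical_or_none(col: str) -> str | None:
    try:
        return canonical_aa(col)
    except KeyError:
        return None


def read_sources(path) -> SourceDataset:
    """Read a source CSV: columns ``sample_id``, ``group``, then one column
    per amino acid (‰).  Non-numeric or missing cells are reported with
    their row and column; unknown column names (after aliasing) are errors.
    """
    df = pd.read_csv(path)
    for required in ("sample_id", "group"):
        if required not in df.columns:
            raise ValueError(f"{path}: malformed header, missing {required!r}")
    aa_map = {}
    for col in df.columns:
        if col in ("sample_id", "group"):
            continue
        aa = _canonical_or_none(col)
        if aa is None:
            raise ValueError(f"{path}: unknown amino-acid column {col!r}")
        aa_map[col] = aa
    _check_numeric(df, list(aa_map), str(path))
    df = df.rename(columns=aa_map)
    samples = {
        str(g): sub[list(aa_map.values())].astype(float)
        for g, sub in df.groupby("group", sort=False)
    }
    return SourceDataset(samples)


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], where: str) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, plus header line
            raise ValueError(
                f"{where}: non-numeric or missing value at row {row}, "
                f"column {col!r}"
            )


def read_consumers(path, default_alpha: float | None = None) -> list[ConsumerSample]:
    """Read a consumer CSV: ``sample_id``, per-amino-acid value columns, and
    optional ``<AA>_sd`` analytical-SD columns.

    Truth columns from simulated-data files (``f(...)``, PTS, MTS, FWL) are
    ignored by the fit path.  Where an ``_sd`` column is absent,
    ``default_alpha`` supplies the analytical SD; if neither is available
    the file is rejected.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: malformed header, missing 'sample_id'")
    value_cols: dict[str, str] = {}
    sd_cols: dict[str, str] = {}
    for col in df.columns:
        if col == "sample_id" or col in _TRUTH_COLS or col.startswith("f("):
            continue
        if col.endswith("_sd"):
            aa = _canonical_or_none(col[:-3])
            if aa is None:
                raise ValueError(f"{path}: unknown amino-acid column {col!r}")
            sd_cols[aa] = col
        else:
            aa = _canonical_or_none(col)
            if aa is None:
                raise ValueError(f"{path}: unknown amino-acid column {col!r}")
            value_cols[aa] = col
    if not value_cols:
        raise ValueError(f"{path}: no amino-acid value columns found")
    _check_numeric(df, list(value_cols.values()) + list(sd_cols.values()), str(path))

    out = []
    for _, row in df.iterrows():
        values = {aa: float(row[c]) for aa, c in value_cols.items()}
        alpha = {}
        for aa in value_cols:
            if aa in sd_cols:
                alpha[aa] = float(row[sd_cols[aa]])
            elif default_alpha is not None:
                alpha[aa] = float(default_alpha)
            else:
                raise ValueError(
                    f"{path}: no analytical SD for {aa} (no '{aa}_sd' column "
                    "and no default alpha configured)"
                )
        out.append(ConsumerSample(id=str(row["sample_id"]), values=values,
                                  alpha=alpha))
    return out


def write_sources(sources: SourceDataset, path) -> None:
    rows = []
    for g in sources.groups:
        df = sources.samples[g]
        for idx, row in df.iterrows():
            rec = {"sample_id": f"{g}_{idx + 1}", "group": g}
            rec.update(row.to_dict())
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_consumers(consumers: Sequence[ConsumerSample], path,
                    include_sd: bool = True) -> None:
    rows = []
    for c in consumers:
        rec = {"sample_id": c.id}
        rec.update(c.values)
        if include_sd:
            rec.update({f"{aa}_sd": v for aa, v in c.alpha.items()})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def wide_to_long(df: pd.DataFrame, id_cols: Sequence[str] = ("sample_id",),
                 value_name: str = "d15N") -> pd.DataFrame:
    """Convert a wide per-amino-acid table to long (tracer, value) format."""
    return df.melt(id_vars=list(id_cols), var_name="tracer",
                   value_name=value_name)


def draws_from_csv(path) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from the long draws CSV
    (chain, iteration, parameter, value)."""
    df = pd.read_csv(path)
    arrays = {}
    for name, sub in df.groupby("parameter", sort=False):
        piv = sub.pivot(index="chain", columns="iteration", values="value")
        arrays[name] = piv.to_numpy(float)
    return PosteriorDraws(arrays=arrays)


@dataclass
class RunManifest:
    """Reproducibility record written next to every run's outputs: input
    files with content hashes, the configuration snapshot, seed, and
    software version."""

    inputs: dict[str, str]
    config: dict
    seed: int
    version: str
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_file(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()

    @classmethod
    def create(cls, input_paths: Mapping[str, str], config: dict,
               seed: int) -> "RunManifest":
        from . import __version__

        return cls(
            inputs={name: cls.hash_file(p) for name, p in input_paths.items()
                    if p is not None},
            config=config,
            seed=int(seed),
            version=__version__,
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def load_run_config(path=None) -> tuple[ModelConfig, PriorConfig, MCMCConfig, dict]:
    """Load a YAML run configuration.

    Recognised top-level keys: ``roles`` (amino acid -> role), ``flags``
    (treat_phe_conservative, nonfractionating_variant, truncate_at_zero),
    ``priors`` (mu_bounds, dispersion_gamma, dirichlet_alpha,
    sigma_prior_on), ``mcmc`` (chains, adapt, burn_in, samples, thin, seed)
    and ``data`` (default_alpha ...).  Missing keys fall back to the
    mesopelagic case-study defaults.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    flags = dict(raw.get("flags", {}))
    config = default_model_config(roles=dict(raw.get("roles", {})), **flags)
    pri = dict(raw.get("priors", {}))
    if "mu_bounds" in pri:
        pri["mu_bounds"] = tuple(pri["mu_bounds"])
    if "dispersion_gamma" in pri:
        pri["dispersion_gamma"] = tuple(pri["dispersion_gamma"])
    if "dirichlet_alpha" in pri and pri["dirichlet_alpha"] is not None:
        pri["dirichlet_alpha"] = np.asarray(pri["dirichlet_alpha"], float)
    priors = PriorConfig(**pri)
    mcmc = MCMCConfig(**dict(raw.get("mcmc", {})))
    extras = dict(raw.get("data", {}))
    return config, priors, mcmc, extras
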