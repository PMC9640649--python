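"""Quantitation-matrix preprocessing: log2 transform and imputation.

Missing cells are replaced by draws from a down-shifted, narrowed normal
distribution fitted per sample column: for a column with observed mean mu
and sample standard deviation sigma, imputed values come from
Normal(mu - shift * sigma, (width * sigma)**2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImputationParams",
    "ColumnError",
    "log2_transform",
    "impute_downshifted",
    "detection_stats",
]


class ColumnError(ValueError):
    """A column has too few observed values to fit the imputation model."""


@dataclass(frozen=True)
class ImputationParams:
    shift: float = 1.8
    width: float = 0.3
    seed: int = 0
    axis: str = "samples"  # impute per sample column (default) or per feature row

    def __post_init__(self):
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.axis not in ("samples", "features"):
            raise ValueError("axis must be 'samples' or 'features'")


def log2_transform(raw_table: pd.DataFrame) -> pd.DataFrame:
    """log2 of raw intensities; zeros become missing, negatives are an error."""
    values = raw_table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative raw intensity")
    out = raw_table.copy().astype(float)
    with np.errstate(divide="ignore"):
        transformed = np.log2(values)
    transformed[values == 0] = np.nan
    out.values[:] = transformed
    return out


def _column_rng(seed: int, column_id: str) -> np.random.Generator:
    # Seeded per column from (seed, sample id) so edits elsewhere in the
    # table do not perturb another column's draws.
    return np.random.default_rng([seed, zlib.crc32(str(column_id).encode())])


def impute_downshifted(
    table: pd.DataFrame, params: ImputationParams | None = None
) -> pd.DataFrame:
    """Replace missing cells by down-shifted normal draws, column-wise.

    Observed cells are never altered.  Each column needs at least two
    observed values; otherwise a :class:`ColumnError` names the offender.
    """
    params = params or ImputationParams()
    work = table if params.axis == "samples" else table.T
    out = work.copy()
    for col in work.columns:
        column = work[col]
        observed = column.dropna()
        n_missing = int(column.isna().sum())
        if len(observed) < 2:
            raise ColumnError(
                f"column {col!r} has {len(observed)} observed values; need >= 2"
            )
        if n_missing == 0:
            continue
        mu = float(observed.mean())
        sigma = float(observed.std(ddof=1))
        rng = _column_rng(params.seed, col)
        draws = rng.normal(
            mu - params.shift * sigma, params.width * sigma, size=n_missing
        )
        out.loc[column.isna(), col] = draws
    return out if params.axis == "samples" else out.T


def detection_stats(
    table: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-feature observed counts and fractions per sample group.

    ``groups`` maps group name -> sample ids and must partition the
    table's columns it references.
    """
    known = set(table.columns)
    seen: set[str] = set()
    for name, samples in groups.items():
        for s in samples:
            if s not in known:
                raise ValueError(f"unknown sample id {s!r} in group {name!r}")
            if s in seen:
                raise ValueError(f"sample id {s!r} assigned to multiple groups")
            seen.add(s)

    out = pd.DataFrame(index=table.index)
    for name, samples in groups.items():
        observed = table[list(samples)].notna()
        out[f"n_obs_{name}"] = observed.sum(axis=1).astype(int)
        out[f"frac_{name}"] = observed.mean(axis=1)
    out["all_missing"] = table[list(seen)].isna().all(axis=1)
    return out
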