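"""Per-subject functional-connectivity matrices.

Functional connectivity between two parcels is the Pearson correlation of
their BOLD time series, mapped through the Fisher z-transform
``z = atanh(r)`` so that edge values are approximately normal and can be
averaged and t-tested across subjects.  Perfectly (anti)correlated columns
are clamped at ``|r| = 1 - 1e-6`` before the transform so degenerate inputs
stay finite; the diagonal is stored as NaN and excluded from every
downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: correlations are clamped at 1 - CLAMP_EPS before atanh
CLAMP_EPS = 1e-6


@dataclass
class BoldTimeSeries:
    """Parcellated BOLD series for one subject: T timepoints x R regions."""

    subject_id: str
    values: np.ndarray
    tr_seconds: float = 3.0
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"subject {self.subject_id}: time series must be 2-D "
                f"(T x R), got shape {self.values.shape}"
            )
        if self.values.shape[0] < 3:
            raise ValidationError(
                f"subject {self.subject_id}: need at least 3 timepoints, "
                f"got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"subject {self.subject_id}: non-finite values in time series"
            )
        if self.tr_seconds <= 0:
            raise ValidationError(
                f"subject {self.subject_id}: tr_seconds must be positive"
            )
        if (
            self.region_names is not None
            and len(self.region_names) != self.values.shape[1]
        ):
            raise ValidationError(
                f"subject {self.subject_id}: {len(self.region_names)} region "
                f"names for {self.values.shape[1]} columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric R x R Fisher-z connectivity matrix; NaN diagonal."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValidationError(
                f"subject {self.subject_id}: FC matrix must be square, "
                f"got shape {self.z.shape}"
            )
        off = ~np.eye(self.z.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValidationError(
                f"subject {self.subject_id}: non-finite off-diagonal entries"
            )
        if not np.allclose(self.z[off], self.z.T[off], atol=1e-10):
            raise ValidationError(
                f"subject {self.subject_id}: FC matrix is not symmetric"
            )
        np.fill_diagonal(self.z, np.nan)

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    def edge_values(self) -> np.ndarray:
        """Upper-triangle z values in row-major edge order."""
        i, j = np.triu_indices(self.n_regions, k=1)
        return self.z[i, j]


@dataclass(frozen=True)
class Edge:
    """Canonical unordered region pair, stored with i < j."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (0 <= self.i < self.j):
            raise ValidationError(
                f"edge requires 0 <= i < j, got ({self.i}, {self.j})"
            )


def fisher_z(r):
    """Fisher z-transform ``atanh(r)`` with clamping at ``|r|=1-1e-6``.

    Accepts scalars or arrays; |r| must not exceed 1.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = arr[~np.isfinite(arr)]
        raise ValidationError(f"non-finite correlation value(s): {bad[:5]}")
    if np.any(np.abs(arr) > 1):
        bad = arr[np.abs(arr) > 1]
        raise ValidationError(
            f"correlation outside [-1, 1]: {bad[:5]}"
        )
    clamped = np.sign(arr) * np.minimum(np.abs(arr), 1.0 - CLAMP_EPS)
    out = np.arctanh(clamped)
    return out if arr.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse transform ``r = tanh(z)``; exact inverse for |r| <= 1-1e-6."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = arr[~np.isfinite(arr)]
        raise ValidationError(f"non-finite z value(s): {bad[:5]}")
    out = np.tanh(arr)
    return out if arr.ndim else float(out)


def compute_fc_matrix(ts: BoldTimeSeries) -> FCMatrix:
    """Pearson-correlate all region pairs and Fisher-z transform.

    A zero-variance column makes the correlation undefined and is rejected
    with the region named (by header label when available, else by index).
    """
    sd = ts.values.std(axis=0)
    if np.any(sd == 0):
        idx = np.flatnonzero(sd == 0)
        names = (
            [ts.region_names[k] for k in idx]
            if ts.region_names is not None
            else [str(k) for k in idx]
        )
        raise ValidationError(
            f"subject {ts.subject_id}: zero-variance region(s) "
            f"{names}; correlation undefined"
        )
    r = np.corrcoef(ts.values, rowvar=False)
    # numerical noise can push |r| marginally past 1
    r = np.clip(r, -1.0, 1.0)
    z = fisher_z(r)
    z = (z + z.T) / 2.0
    return FCMatrix(subject_id=ts.subject_id, z=z)


def edge_index(i: int, j: int, n_regions: int) -> int:
    """Linear position of edge (i, j) in row-major upper-triangle order."""
    if not (0 <= i < j < n_regions):
        raise ValidationError(
            f"edge ({i}, {j}) invalid for R={n_regions}: need 0 <= i < j < R"
        )
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


def edge_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) arrays of all R(R-1)/2 edges in row-major order."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


# ---------------------------------------------------------------------------
# Text I/O (TSV only; one file per subject, filename stem = subject id)
# ---------------------------------------------------------------------------

def read_time_series(path: str | Path, tr_seconds: float = 3.0) -> BoldTimeSeries:
    """Read a T x R TSV with a header row of region names."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return BoldTimeSeries(
        subject_id=path.stem,
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_names=[str(c) for c in df.columns],
    )


def write_time_series(ts: BoldTimeSeries, path: str | Path) -> None:
    names = ts.region_names or [f"region_{k}" for k in range(ts.n_regions)]
    pd.DataFrame(ts.values, columns=names).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_fc_matrix(path: str | Path) -> FCMatrix:
    """Read an R x R TSV with header + row labels; 'NA' diagonal."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(subject_id=path.stem, z=df.to_numpy(dtype=float))


def write_fc_matrix(fc: FCMatrix, path: str | Path,
                    region_names: Sequence[str] | None = None) -> None:
    names = list(region_names) if region_names is not None else [
        f"region_{k}" for k in range(fc.n_regions)
    ]
    pd.DataFrame(fc.z, index=names, columns=names).to_csv(
        path, sep="\t", na_rep="NA", float_format="%.10g"
    )
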