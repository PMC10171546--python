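"""Connectome construction and file I/O.

Builds per-scan connectivity matrices from the two imaging-derived inputs the
pipeline consumes — regional BOLD time series (functional) and streamline-count
matrices with node volumes (structural) — applies motion quality control, and
reads/writes the plain-text interchange formats used throughout the package.

Functional connectivity is the Pearson correlation between every pair of
regional time series. Structural connectivity scales each streamline count by
the inverse of the two node volumes (the ``invnodevol`` convention,
``2 / (v_i + v_j)`` per streamline) so that larger regions, which accumulate
more streamlines by construction, are not trivially better connected.

Matrices are stored as whitespace-delimited numeric text with a one-label-per
-line sidecar file; phenotypes as CSV. Both are language-neutral and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("connectodev")

#: Columns a phenotype table must provide, in canonical order.
PHENOTYPE_COLUMNS = (
    "scan_id",
    "subject_id",
    "wave",
    "age",
    "group",
    "sex",
    "fd",
    "scanner",
    "medicated",
)

GROUPS = ("ADHD", "control")
SCANNERS = ("pre_upgrade", "post_upgrade")

#: Default motion-exclusion ceiling: scans with mean framewise displacement
#: strictly greater than this many millimetres are dropped.
FD_MAX_MM = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_labels(labels: Sequence[str], n: int) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} region labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("region labels must be unique")
    return labels


@dataclass
class RoiTimeSeries:
    """Regional BOLD time series for one scan: ``data`` is T timepoints x N regions."""

    scan_id: str
    data: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x N) array")
        t, n = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        self.region_labels = _check_labels(self.region_labels, n)

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Weighted symmetric N x N connectivity for one scan, zero diagonal.

    ``modality`` is ``"functional"`` (Pearson r, entries in [-1, 1]) or
    ``"structural"`` (volume-scaled streamline counts, entries >= 0).
    """

    scan_id: str
    modality: str
    W: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.W, self.W.T, atol=1e-10):
            raise ValueError(f"connectivity matrix for {self.scan_id!r} is not symmetric")
        if np.any(np.abs(np.diag(self.W)) > 1e-12):
            raise ValueError("connectivity matrix diagonal must be zero")
        if self.modality == "functional" and np.any(np.abs(self.W) > 1 + 1e-9):
            raise ValueError("functional connectivity entries must lie in [-1, 1]")
        if self.modality == "structural" and np.any(self.W < 0):
            raise ValueError("structural connectivity entries must be non-negative")
        self.region_labels = _check_labels(self.region_labels, self.W.shape[0])

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]


@dataclass
class NodeVolumes:
    """Per-region grey-matter volumes in mm^3 (all strictly positive)."""

    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1:
            raise ValueError("node volumes must be a 1-D vector")
        if np.any(self.v <= 0):
            raise ValueError("node volumes must be strictly positive")


@dataclass
class ScanRecord:
    """One scanning session: identity, wave, age, group and nuisance covariates."""

    scan_id: str
    subject_id: str
    wave: int
    age: float
    group: str
    sex: str
    fd: float
    scanner: str
    medicated: bool

    def __post_init__(self) -> None:
        self.wave = int(self.wave)
        self.age = float(self.age)
        self.fd = float(self.fd)
        self.medicated = bool(self.medicated)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.scanner not in SCANNERS:
            raise ValueError(f"scanner must be one of {SCANNERS}, got {self.scanner!r}")
        if self.fd < 0:
            raise ValueError("framewise displacement must be >= 0")


def validate_records(
    records: Iterable[ScanRecord], age_range: tuple[float, float] = (8.0, 16.0)
) -> None:
    """Check cross-record invariants: unique (subject, wave), plausible ages."""
    seen: set[tuple[str, int]] = set()
    lo, hi = age_range
    for r in records:
        key = (r.subject_id, r.wave)
        if key in seen:
            raise ValueError(f"duplicate (subject_id, wave) pair {key}")
        seen.add(key)
        if not lo <= r.age <= hi:
            raise ValueError(
                f"scan {r.scan_id!r}: age {r.age} outside plausible range {age_range}"
            )


# ---------------------------------------------------------------------------
# Connectivity construction
# ---------------------------------------------------------------------------


def compute_functional_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity for one scan.

    ``W[i, j]`` is the Pearson r between the time series of regions i and j;
    the diagonal is set to zero. Zero-variance regions make the correlation
    undefined and raise, naming the offending region.
    """
    data = ts.data
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = ", ".join(ts.region_labels[i] for i in flat[:5])
        raise ValueError(f"zero-variance time series for region(s): {names}")
    w = np.corrcoef(data, rowvar=False)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(ts.scan_id, "functional", w, list(ts.region_labels))


def scale_structural_matrix(
    counts: np.ndarray,
    vols: NodeVolumes,
    scan_id: str = "",
    region_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Volume-scaled structural connectivity from a streamline-count matrix.

    Each edge weight is ``counts[i, j] * 2 / (v_i + v_j)``: every streamline
    contributes the inverse of the mean volume of its two endpoint regions.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("streamline-count matrix must be square")
    if not np.array_equal(counts, counts.T):
        raise ValueError("streamline-count matrix must be symmetric")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be non-negative")
    n = counts.shape[0]
    if vols.v.shape[0] != n:
        raise ValueError(
            f"{vols.v.shape[0]} node volumes for a {n}-region count matrix"
        )
    vsum = vols.v[:, None] + vols.v[None, :]
    w = counts * 2.0 / vsum
    np.fill_diagonal(w, 0.0)
    if region_labels is None:
        region_labels = [f"region_{i}" for i in range(n)]
    return ConnectivityMatrix(scan_id, "structural", w, list(region_labels))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_filter_scans(
    records: Sequence[ScanRecord], fd_max: float = FD_MAX_MM
) -> tuple[list[ScanRecord], list[dict]]:
    """Drop scans whose mean framewise displacement exceeds ``fd_max`` (strictly).

    Returns the retained records and an exclusion log, one dict per dropped
    scan with the scan id, its fd and the reason. Idempotent: re-filtering the
    retained list excludes nothing further.
    """
    if fd_max <= 0:
        raise ValueError("fd_max must be positive")
    kept: list[ScanRecord] = []
    excluded: list[dict] = []
    for r in records:
        if r.fd > fd_max:
            excluded.append(
                {
                    "scan_id": r.scan_id,
                    "fd": r.fd,
                    "reason": f"mean framewise displacement {r.fd:.3f} mm > {fd_max} mm",
                }
            )
        else:
            kept.append(r)
    if excluded:
        logger.info("QC excluded %d of %d scans (fd > %g mm)", len(excluded), len(records), fd_max)
    return kept, excluded


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _labels_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels")


def write_matrix(m: ConnectivityMatrix, path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write a connectivity matrix as delimited text plus a label sidecar file."""
    path = Path(path)
    np.savetxt(path, m.W, fmt="%.17g")
    lp = Path(labels_path) if labels_path is not None else _labels_path(path)
    lp.write_text("\n".join(m.region_labels) + "\n")


def read_matrix(
    path: str | Path,
    modality: str,
    scan_id: str | None = None,
    labels_path: str | Path | None = None,
) -> ConnectivityMatrix:
    """Read a delimited-text matrix; symmetry and shape are validated on read."""
    path = Path(path)
    w = np.loadtxt(path, ndmin=2)
    lp = Path(labels_path) if labels_path is not None else _labels_path(path)
    if lp.exists():
        labels = [ln for ln in lp.read_text().splitlines() if ln.strip()]
    else:
        labels = [f"region_{i}" for i in range(w.shape[0])]
    if len(labels) != w.shape[0]:
        raise ValueError(
            f"{path}: {w.shape[0]}x{w.shape[1]} matrix but {len(labels)} labels in {lp}"
        )
    return ConnectivityMatrix(scan_id or path.stem, modality, w, labels)


def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Phenotype records as a DataFrame in canonical column order."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in PHENOTYPE_COLUMNS} for r in records],
        columns=list(PHENOTYPE_COLUMNS),
    )


def frame_to_records(df: pd.DataFrame) -> list[ScanRecord]:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing column(s): {', '.join(missing)}")
    records = [
        ScanRecord(**{c: row[c] for c in PHENOTYPE_COLUMNS}) for _, row in df.iterrows()
    ]
    validate_records(records)
    return records


def write_phenotypes(records: Sequence[ScanRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> list[ScanRecord]:
    """Read a phenotype CSV; missing columns and duplicate (subject, wave) raise."""
    df = pd.read_csv(path)
    if "medicated" in df.columns:
        df["medicated"] = df["medicated"].astype(bool)
    return frame_to_records(df)
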