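"""Per-subject Pearson functional connectivity and the pathway F matrix.

Functional connectivity between two regions is the Pearson correlation of
their time courses.  For a pathway instance with edges ``(e_1 .. e_n)``, the
cohort's Fisher-z-transformed correlations on those edges form the samples ×
edges connectivity matrix F (entries ``R_ij``) consumed by the exhaustive
subset search in :mod:`brainpath.activity`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import ParcellationLabels, PathwayInstance

__all__ = [
    "ConnectivityMatrix",
    "PathwayConnectivityMatrix",
    "RegionTimeSeries",
    "build_f_matrix",
    "fisher_z",
    "mean_connectivity",
    "pearson_connectivity",
    "read_cohort_manifest",
    "read_time_series",
    "write_connectivity_matrix",
    "write_time_series",
]

#: |r| is clipped to this bound before arctanh so z stays finite at r = +/-1
R_CLIP = 1.0 - 1e-7


@dataclass
class RegionTimeSeries:
    """Region-averaged signals for one subject: timepoints × regions."""

    subject_id: str
    values: np.ndarray
    labels: ParcellationLabels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D timepoints × regions array")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.values.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.subject_id}: {self.values.shape[1]} columns but "
                f"{len(self.labels)} parcellation labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.subject_id}: non-finite values in time series")


@dataclass
class ConnectivityMatrix:
    """Symmetric region × region Pearson r matrix for one subject."""

    subject_id: str
    r: np.ndarray
    labels: ParcellationLabels

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.labels)
        if self.r.shape != (n, n):
            raise ValueError(f"{self.subject_id}: matrix shape {self.r.shape} != ({n},{n})")
        if not np.isfinite(self.r).all():
            raise ValueError(f"{self.subject_id}: non-finite correlation values")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError(f"{self.subject_id}: correlation matrix not symmetric")

    def edge_r(self, region_a: str, region_b: str) -> float:
        return float(self.r[self.labels.index(region_a), self.labels.index(region_b)])

    @property
    def n_pairs(self) -> int:
        return self.labels.n_pairs


@dataclass
class PathwayConnectivityMatrix:
    """Samples × pathway-edges matrix of Fisher-z values with group labels."""

    pathway_id: str
    z: np.ndarray
    sample_ids: tuple[str, ...]
    group_labels: np.ndarray
    edge_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.z.shape != (len(self.sample_ids), len(self.edge_names)):
            raise ValueError("F matrix shape does not match sample/edge names")
        if self.group_labels.shape != (len(self.sample_ids),):
            raise ValueError("one group label required per sample")
        if len(np.unique(self.group_labels)) != 2:
            raise ValueError("exactly two groups required")

    @property
    def n_edges(self) -> int:
        return len(self.edge_names)


def pearson_connectivity(ts: RegionTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of every region pair over the full time series.

    A zero-variance region column has no defined correlation; it is an error
    naming the region rather than a silent NaN.
    """
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.labels.names[i] for i in dead)
        raise ValueError(f"{ts.subject_id}: zero-variance region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    # corrcoef can drift to 1 + eps on perfectly dependent columns
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, r=r, labels=ts.labels)


def fisher_z(r):
    """Fisher z-transformation z = arctanh(r), variance-stabilizing for Pearson r.

    ``|r|`` is clipped to ``1 - 1e-7`` first so degenerate perfect correlations
    map to a large finite z instead of infinity.  Accepts scalars or arrays;
    values outside [-1, 1] are an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def mean_connectivity(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of subject matrices (group-level display convenience)."""
    if not matrices:
        raise ValueError("no matrices to average")
    labels = matrices[0].labels
    stack = np.stack([m.r for m in matrices])
    return ConnectivityMatrix(subject_id="<group mean>", r=stack.mean(axis=0), labels=labels)


def build_f_matrix(
    cohort: Sequence[ConnectivityMatrix],
    instance: PathwayInstance,
    group_labels: Sequence,
) -> PathwayConnectivityMatrix:
    """Assemble a pathway's connectivity (F) matrix across a cohort.

    Row i holds subject i's Fisher-z values on the pathway's edges, in edge
    order; rows follow cohort order.
    """
    if len(cohort) != len(group_labels):
        raise ValueError("one group label required per subject")
    if not cohort:
        raise ValueError("empty cohort")
    labels = cohort[0].labels
    idx = np.array(
        [(labels.index(a), labels.index(b)) for a, b in instance.edges], dtype=int
    )
    rows = np.stack([conn.r[idx[:, 0], idx[:, 1]] for conn in cohort])
    return PathwayConnectivityMatrix(
        pathway_id=instance.id,
        z=fisher_z(rows),
        sample_ids=tuple(c.subject_id for c in cohort),
        group_labels=np.asarray(group_labels),
        edge_names=instance.edge_names,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_time_series(
    path: str | Path, labels: ParcellationLabels, subject_id: str | None = None
) -> RegionTimeSeries:
    """Read one subject's TSV (rows = timepoints, header = region names)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(labels.names):
        raise ValueError(f"{path}: header does not match the parcellation labels")
    return RegionTimeSeries(
        subject_id=subject_id or Path(path).stem,
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def write_time_series(ts: RegionTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.labels.names)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_connectivity_matrix(conn: ConnectivityMatrix, path: str | Path) -> None:
    names = list(conn.labels.names)
    pd.DataFrame(conn.r, index=names, columns=names).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def read_cohort_manifest(
    path: str | Path, labels: ParcellationLabels
) -> tuple[list[RegionTimeSeries], np.ndarray]:
    """Read a cohort manifest TSV (columns subject_id, file, group).

    ``file`` paths are resolved relative to the manifest's directory.  Returns
    the subjects in manifest order with their group labels.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"subject_id", "file", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cohort = [
        read_time_series(base / row.file, labels, subject_id=str(row.subject_id))
        for row in df.itertuples()
    ]
    return cohort, df["group"].to_numpy()
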