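"""Pearson functional connectivity and edge-vector (de)flattening.

Functional connectivity (FC) is summarized as the sample Pearson correlation
between every pair of regional time series. For downstream tabular models and
harmonization, the symmetric R x R matrix is flattened to its upper triangle
(excluding the diagonal) in row-major order: R(R-1)/2 features, 6,670 for the
116-region AAL parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "EdgeVector",
    "pearson_fc",
    "flatten_upper",
    "unflatten",
    "upper_pairs",
    "edge_feature_names",
    "read_timeseries_tsv",
    "write_fc_csv",
    "fisher_z",
    "inverse_fisher_z",
]

SYMMETRY_TOL = 1e-12


def default_region_labels(n_regions: int) -> list[str]:
    return [f"ROI{i + 1}" for i in range(n_regions)]


@dataclass
class ROITimeSeries:
    """T x R matrix of regional signals for one subject."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x R matrix")
        if not self.region_labels:
            self.region_labels = default_region_labels(self.values.shape[1])
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length must match number of columns")
        if not np.isfinite(self.values).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R Pearson matrix with unit diagonal."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        R = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != R:
            raise ValueError("connectivity matrix must be square")
        if not self.region_labels:
            self.region_labels = default_region_labels(R)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError(f"subject {self.subject_id}: matrix not symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError(f"subject {self.subject_id}: diagonal must be exactly 1")
        if v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError(f"subject {self.subject_id}: entries outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Row-major upper-triangle flattening of a connectivity matrix."""

    subject_id: str
    values: np.ndarray
    index_map: list[tuple[int, int]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.index_map):
            raise ValueError("values and index_map length mismatch")


def upper_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) index pairs."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def edge_feature_names(region_labels: list[str]) -> list[str]:
    return [f"{region_labels[i]}__{region_labels[j]}" for i, j in upper_pairs(len(region_labels))]


def pearson_fc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the regional time series.

    Uses all T timepoints of the subject; T may differ between subjects
    without affecting comparability of the resulting matrices.
    """
    X = ts.values
    T, R = X.shape
    if R < 2:
        raise ValueError("need at least 2 regions for connectivity")
    if T < 3:
        raise ValueError(f"subject {ts.subject_id}: need T >= 3 timepoints, got {T}")
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = [ts.region_labels[i] for i in dead]
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance region(s): {', '.join(labels)}"
        )
    corr = np.corrcoef(X, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(ts.subject_id, corr, list(ts.region_labels))


def flatten_upper(fc: ConnectivityMatrix) -> EdgeVector:
    """Flatten the upper triangle (excluding diagonal), row-major."""
    fc.validate()
    R = fc.n_regions
    iu, ju = np.triu_indices(R, k=1)
    return EdgeVector(fc.subject_id, fc.values[iu, ju], upper_pairs(R))


def unflatten(
    v: np.ndarray | EdgeVector,
    n_regions: int,
    subject_id: str = "",
    region_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    if isinstance(v, EdgeVector):
        subject_id = subject_id or v.subject_id
        v = v.values
    v = np.asarray(v, dtype=float).ravel()
    expected = n_regions * (n_regions - 1) // 2
    if v.size != expected:
        raise ValueError(f"edge vector has length {v.size}, expected {expected} for R={n_regions}")
    mat = np.eye(n_regions)
    iu, ju = np.triu_indices(n_regions, k=1)
    mat[iu, ju] = v
    mat[ju, iu] = v
    return ConnectivityMatrix(subject_id, mat, region_labels or [])


def fisher_z(r: np.ndarray, clip: float = 0.999999) -> np.ndarray:
    """Fisher z-transform with clipping away from |r| = 1."""
    return np.arctanh(np.clip(r, -clip, clip))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


# -- file I/O -----------------------------------------------------------------


def read_timeseries_tsv(path, subject_id: str | None = None) -> ROITimeSeries:
    """Read a T x R TSV with a header row of region labels."""
    df = pd.read_csv(path, sep="\t")
    sid = subject_id or str(path).rsplit("/", 1)[-1].split(".")[0]
    return ROITimeSeries(sid, df.to_numpy(dtype=float), [str(c) for c in df.columns])


def write_timeseries_tsv(ts: ROITimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(path, sep="\t", index=False)


def write_fc_csv(fc: ConnectivityMatrix, path) -> None:
    pd.DataFrame(fc.values, columns=fc.region_labels).to_csv(path, index=False)


def read_fc_csv(path, subject_id: str | None = None) -> ConnectivityMatrix:
    df = pd.read_csv(path)
    sid = subject_id or str(path).rsplit("/", 1)[-1].split(".")[0]
    vals = df.to_numpy(dtype=float)
    # tolerate round-trip noise from text serialization
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(sid, vals, [str(c) for c in df.columns])


def edge_table(fcs: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Cohort edge-vector table: one row per subject, R(R-1)/2 columns."""
    if not fcs:
        raise ValueError("no connectivity matrices given")
    labels = fcs[0].region_labels
    rows = [flatten_upper(fc).values for fc in fcs]
    df = pd.DataFrame(np.vstack(rows), columns=edge_feature_names(labels))
    df.insert(0, "subject_id", [fc.subject_id for fc in fcs])
    return df
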