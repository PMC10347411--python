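"""Synthetic multi-site rs-fMRI cohorts with a planted brain-age signal.

The generator emulates the statistical shape of a multi-site aging cohort:
a 116-region parcellation, several acquisition sites with location/scale
effects on connectivity, chronological ages spanning late adulthood, and
diagnostic groups whose latent "brain age" is offset from chronological age
(accelerated aging). The planted structure is:

    z_ij(subject) = base_ij + beta1_ij * zscore(brain_age)   [signal edges]
                    + gamma_site + delta_site * eps_ij        [all edges]

on the Fisher-z scale, back-transformed to a valid correlation matrix from
which regional time series are simulated. ``brain_age = age + Delta_group +
jitter`` is recorded in provenance only; the pipeline never sees it.

Site effects follow the location/scale model that empirical-Bayes
harmonization assumes: an additive per-site shift and a multiplicative
per-site inflation of the subject-level residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityMatrix,
    ROITimeSeries,
    default_region_labels,
    write_timeseries_tsv,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "PlantedParameters",
    "plant_parameters",
    "sample_connectivity_target",
    "simulate_timeseries",
    "generate_cohort",
    "default_cohort_spec",
    "write_cohort",
]

DEFAULT_GROUPS = (
    ("HC", 0.0),
    ("SMC", 1.0),
    ("EMCI", 2.0),
    ("MCI", 3.0),
    ("LMCI", 4.0),
    ("AD", 5.0),
)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    delta: float  # planted brain-age offset in years
    n: int | None = None  # overrides CohortSpec.n_subjects_per_group


@dataclass(frozen=True)
class CohortSpec:
    n_subjects_per_group: int = 40
    groups: tuple[GroupSpec, ...] = tuple(GroupSpec(g, d) for g, d in DEFAULT_GROUPS)
    n_regions: int = 116
    n_sites: int = 8
    age_range: tuple[float, float] = (51.0, 97.0)
    n_signal_edges: int = 60
    signal_slope_range: tuple[float, float] = (0.2, 0.4)
    site_shift_sd: float = 0.1
    site_scale_sd: float = 0.1
    subject_noise_sd: float = 0.03
    brain_age_jitter_sd: float = 1.0
    timeseries_length_range: tuple[int, int] = (120, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("age_range must be an increasing interval")
        max_edges = self.n_regions * (self.n_regions - 1) // 2
        if not (0 <= self.n_signal_edges <= max_edges):
            raise ValueError(f"n_signal_edges must be in [0, {max_edges}]")
        for g in self.groups:
            if not np.isfinite(g.delta):
                raise ValueError(f"group {g.label}: offset must be finite")
        if self.timeseries_length_range[0] > self.timeseries_length_range[1]:
            raise ValueError("timeseries_length_range must be ordered")
        for name in ("site_shift_sd", "site_scale_sd", "subject_noise_sd", "brain_age_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def group_size(self, g: GroupSpec) -> int:
        return self.n_subjects_per_group if g.n is None else g.n


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    brain_age: float  # latent; provenance only
    sex: str
    site: str
    group: str
    n_timepoints: int


@dataclass
class PlantedParameters:
    """Cohort-level ground truth, fixed once from CohortSpec.seed."""

    base_z: np.ndarray  # (R, R) symmetric Fisher-z baseline, 0 diagonal
    signal_edges: np.ndarray  # (n_signal, 2) upper-triangle pairs
    slopes: np.ndarray  # (n_signal,) beta1 per signal edge
    site_labels: list[str]
    site_shift: np.ndarray  # gamma_s
    site_scale: np.ndarray  # delta_s (positive)


@dataclass
class Cohort:
    spec: CohortSpec
    records: list[SubjectRecord]
    timeseries: list[ROITimeSeries]
    planted: PlantedParameters

    def phenotypes(self) -> pd.DataFrame:
        """Pipeline-facing phenotype table (no latent brain age)."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "site": [r.site for r in self.records],
                "group": [r.group for r in self.records],
            }
        )

    def provenance(self) -> pd.DataFrame:
        """Per-subject latent truth; for evaluation only."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "age": [r.age for r in self.records],
                "brain_age": [r.brain_age for r in self.records],
                "group": [r.group for r in self.records],
                "site": [r.site for r in self.records],
                "n_timepoints": [r.n_timepoints for r in self.records],
            }
        )

    def planted_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        edges = pd.DataFrame(
            {
                "region_i": self.planted.signal_edges[:, 0],
                "region_j": self.planted.signal_edges[:, 1],
                "slope": self.planted.slopes,
            }
        )
        sites = pd.DataFrame(
            {
                "site": self.planted.site_labels,
                "shift": self.planted.site_shift,
                "scale": self.planted.site_scale,
            }
        )
        return edges, sites


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study conditions: a control-heavy six-group cohort.

    471 of the emulated cohort's subjects are controls, so the default plants
    400 controls and 40 subjects per patient group.
    """
    groups = tuple(
        GroupSpec(g, d, n=400 if g == "HC" else 40) for g, d in DEFAULT_GROUPS
    )
    return replace(CohortSpec(groups=groups, seed=seed), **overrides)


def _zscore_age(brain_age: float | np.ndarray, age_range: tuple[float, float]) -> np.ndarray:
    lo, hi = age_range
    center = (lo + hi) / 2.0
    sd = (hi - lo) / np.sqrt(12.0)  # SD of uniform ages over the range
    return (np.asarray(brain_age) - center) / sd


def plant_parameters(spec: CohortSpec) -> PlantedParameters:
    """Draw the cohort-level ground truth deterministically from spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = spec.n_regions

    # low-rank factor structure gives a realistic, modest FC baseline
    k = min(5, R - 1)
    W = rng.normal(0.0, 1.0, size=(R, k))
    cov = W @ W.T + np.diag(rng.uniform(3.0, 6.0, size=R) * k)
    d = np.sqrt(np.diag(cov))
    base_r = cov / np.outer(d, d)
    base_z = np.arctanh(np.clip(base_r, -0.999, 0.999))
    np.fill_diagonal(base_z, 0.0)

    iu, ju = np.triu_indices(R, k=1)
    n_pairs = iu.size
    chosen = rng.choice(n_pairs, size=spec.n_signal_edges, replace=False)
    signal_edges = np.column_stack([iu[chosen], ju[chosen]]).astype(int)
    slopes = rng.uniform(*spec.signal_slope_range, size=spec.n_signal_edges)

    site_labels = [f"site{s + 1:02d}" for s in range(spec.n_sites)]
    site_shift = rng.normal(0.0, spec.site_shift_sd, size=spec.n_sites)
    site_scale = np.exp(rng.normal(0.0, spec.site_scale_sd, size=spec.n_sites))
    return PlantedParameters(base_z, signal_edges, slopes, site_labels, site_shift, site_scale)


def _repair_correlation(mat: np.ndarray, subject_id: str, eps: float = 1e-6) -> np.ndarray:
    """Project to the nearest valid correlation matrix by eigenvalue clipping."""
    sym = (mat + mat.T) / 2.0
    w, V = np.linalg.eigh(sym)
    if w.min() < eps:
        w = np.clip(w, eps, None)
        sym = (V * w) @ V.T
    d = np.diag(sym)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError(f"subject {subject_id}: correlation repair failed")
    sym = sym / np.sqrt(np.outer(d, d))
    sym = (sym + sym.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    return np.clip(sym, -1.0, 1.0)


def sample_connectivity_target(
    record: SubjectRecord,
    spec: CohortSpec,
    rng: np.random.Generator,
    planted: PlantedParameters | None = None,
) -> ConnectivityMatrix:
    """Sample this subject's ground-truth correlation matrix."""
    if planted is None:
        planted = plant_parameters(spec)
    R = spec.n_regions
    z = planted.base_z.copy()

    if len(planted.signal_edges):
        zage = float(_zscore_age(record.brain_age, spec.age_range))
        i, j = planted.signal_edges[:, 0], planted.signal_edges[:, 1]
        z[i, j] += planted.slopes * zage
        z[j, i] = z[i, j]

    s = planted.site_labels.index(record.site)
    iu, ju = np.triu_indices(R, k=1)
    eps_edges = rng.normal(0.0, spec.subject_noise_sd, size=iu.size)
    noise = np.zeros((R, R))
    noise[iu, ju] = eps_edges
    noise = noise + noise.T
    z = z + planted.site_scale[s] * noise + planted.site_shift[s] * (1.0 - np.eye(R))

    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    r = _repair_correlation(r, record.subject_id)
    return ConnectivityMatrix(record.subject_id, r, default_region_labels(R))


def simulate_timeseries(
    target: ConnectivityMatrix | np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    subject_id: str = "",
) -> ROITimeSeries:
    """Simulate T x R signals whose sample correlation converges to target.

    White Gaussian noise is colored by a symmetric square-root factor of the
    target matrix (eigendecomposition; valid for any PSD target).
    """
    if isinstance(target, ConnectivityMatrix):
        subject_id = subject_id or target.subject_id
        labels = target.region_labels
        C = target.values
    else:
        C = np.asarray(target, dtype=float)
        labels = default_region_labels(C.shape[0])
    if not np.all(np.isfinite(C)):
        raise ValueError(f"subject {subject_id}: non-finite target matrix")
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(f"subject {subject_id}: target matrix is not positive semi-definite")
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((n_timepoints, C.shape[0]))
    X = Z @ factor.T
    return ROITimeSeries(subject_id or "synthetic", X, list(labels))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically generate the full cohort from spec.seed."""
    spec.validate()
    planted = plant_parameters(spec)
    rng = np.random.default_rng([spec.seed, 1])

    total_n = sum(spec.group_size(g) for g in spec.groups)
    if total_n < 3 * spec.n_sites:
        raise ValueError(
            f"{total_n} subjects cannot give every one of {spec.n_sites} sites >= 3 subjects"
        )

    records: list[SubjectRecord] = []
    idx = 0
    for g in spec.groups:
        for _ in range(spec.group_size(g)):
            age = float(rng.uniform(*spec.age_range))
            jitter = float(rng.normal(0.0, spec.brain_age_jitter_sd))
            T = int(rng.integers(spec.timeseries_length_range[0], spec.timeseries_length_range[1] + 1))
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{idx + 1:04d}",
                    age=age,
                    brain_age=age + g.delta + jitter,
                    sex="M" if rng.random() < 0.5 else "F",
                    site="",  # assigned below
                    group=g.label,
                    n_timepoints=T,
                )
            )
            idx += 1

    # round-robin site assignment over a shuffled order keeps sites balanced
    order = rng.permutation(total_n)
    for pos, subj_idx in enumerate(order):
        records[subj_idx].site = planted.site_labels[pos % spec.n_sites]

    timeseries: list[ROITimeSeries] = []
    for rec in records:
        target = sample_connectivity_target(rec, spec, rng, planted)
        timeseries.append(simulate_timeseries(target, rec.n_timepoints, rng, rec.subject_id))
    return Cohort(spec, records, timeseries, planted)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write per-subject TSVs plus phenotype and provenance CSVs."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries_tsv(ts, ts_dir / f"{ts.subject_id}.tsv")
    cohort.phenotypes().to_csv(out / "phenotypes.csv", index=False)
    cohort.provenance().to_csv(out / "provenance_subjects.csv", index=False)
    edges, sites = cohort.planted_tables()
    edges.to_csv(out / "provenance_signal_edges.csv", index=False)
    sites.to_csv(out / "provenance_sites.csv", index=False)
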