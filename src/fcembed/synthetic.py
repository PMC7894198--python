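"""Synthetic rs-fMRI cohort generator with planted group connectivity.

Real resting-state studies of Alzheimer's progression compare groups of
subjects (healthy controls, mild cognitive impairment, Alzheimer's disease)
whose inter-regional BOLD correlation structure differs.  Because the only
statistic the downstream pipeline consumes is the Pearson correlation
matrix of the ROI time series, the simplest faithful generative stand-in
is a zero-mean multivariate Gaussian per subject whose *population*
correlation matrix carries a group-dependent "planted module": a block of
ROIs whose mutual correlation weakens linearly with disease stage
(monotone hypoconnectivity), while all off-module structure is identical
across groups.

Geometry defaults to the 130-timepoint x 116-ROI matrices produced by an
AAL-atlas parcellation of a standard ADNI-style acquisition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import STAGE_SIMULATE, rng_for

__all__ = [
    "CohortConfig",
    "TimeSeriesMatrix",
    "build_group_covariance",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_EIG_FLOOR = 1e-6  # eigenvalue clip used for positive-definiteness repair


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition description for one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per diagnostic label.
    n_rois, n_timepoints
        Matrix geometry (columns = ROIs, rows = time points).
    effect_size
        Total drop in within-module correlation from the first to the last
        group, in correlation units.  Group ``g`` of ``G`` gets within-module
        correlation ``base_correlation - g * effect_size / (G - 1)``.
    module_size
        Number of ROIs in the planted module (the first ``module_size``
        ROI indices).
    base_correlation
        Within-module correlation of the reference (first) group.
    noise_sd
        Marginal standard deviation of every ROI signal.
    labels
        Ordered diagnostic labels; order defines the progression axis.
    seed
        Master seed; all cohort randomness derives from it.
    """

    n_per_group: int = 31
    n_rois: int = 116
    n_timepoints: int = 130
    effect_size: float = 0.5
    module_size: int = 10
    base_correlation: float = 0.45
    noise_sd: float = 1.0
    labels: tuple[str, ...] = ("HC", "MCI", "AD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_rois < 2 or self.n_timepoints < 2:
            raise ValueError("cohort dimensions must be positive (>=2 timepoints/ROIs)")
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError(f"effect_size must lie in [0, 1), got {self.effect_size}")
        if not -1.0 < self.base_correlation < 1.0:
            raise ValueError("base_correlation must lie in (-1, 1)")
        if abs(self.base_correlation) + self.effect_size >= 1.0:
            raise ValueError("|base_correlation| + effect_size must be < 1 so every "
                             "group correlation stays inside (-1, 1)")
        if not 0 <= self.module_size <= self.n_rois:
            raise ValueError("module_size must be between 0 and n_rois")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.labels) < 1:
            raise ValueError("at least one label is required")

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def group_correlation(self, group_index: int) -> float:
        """Population within-module correlation of one group."""
        if not 0 <= group_index < self.n_groups:
            raise ValueError(f"group_index {group_index} out of range")
        if self.n_groups == 1:
            return self.base_correlation
        rho = self.base_correlation - group_index * self.effect_size / (self.n_groups - 1)
        if not -1.0 < rho < 1.0:
            raise ValueError(f"target correlation {rho} leaves (-1, 1)")
        return rho

    def roi_names(self) -> list[str]:
        return [f"ROI{i + 1:03d}" for i in range(self.n_rois)]


@dataclass
class TimeSeriesMatrix:
    """One subject's T x N ROI signal matrix (rows = time points)."""

    subject_id: str
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T x N) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: non-finite values")
        var = self.values.var(axis=0)
        if np.any(var <= 0):
            bad = int(np.flatnonzero(var <= 0)[0])
            raise ValueError(f"subject {self.subject_id}: ROI column {bad} has zero variance")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _nearest_pd_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor, then rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] > _EIG_FLOOR:
        return sym
    vals = np.clip(vals, _EIG_FLOOR, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_group_covariance(config: CohortConfig, group_index: int) -> np.ndarray:
    """Population covariance of one diagnostic group.

    Off-module entries are identical (zero) across groups; the within-module
    off-diagonal correlation equals the group's target correlation.  The
    constant-correlation block is positive definite whenever the target
    exceeds ``-1/(module_size-1)``; otherwise the matrix is projected to the
    nearest positive-definite correlation matrix.
    """
    rho = config.group_correlation(group_index)
    corr = np.eye(config.n_rois)
    m = config.module_size
    if m >= 2:
        block = np.full((m, m), rho)
        np.fill_diagonal(block, 1.0)
        corr[:m, :m] = block
    corr = _nearest_pd_correlation(corr)
    return corr * config.noise_sd**2


def generate_cohort(config: CohortConfig) -> tuple[list[TimeSeriesMatrix], np.ndarray]:
    """Draw the full labeled cohort.

    Each subject's rows are i.i.d. draws from the zero-mean multivariate
    normal of that subject's group.  Reproducible bit-for-bit from
    ``config.seed``; each subject consumes its own sub-seeded generator so
    order of generation is irrelevant.
    """
    subjects: list[TimeSeriesMatrix] = []
    labels: list[str] = []
    chol = {g: np.linalg.cholesky(build_group_covariance(config, g))
            for g in range(config.n_groups)}
    idx = 0
    for g, label in enumerate(config.labels):
        for _ in range(config.n_per_group):
            rng = rng_for(config.seed, STAGE_SIMULATE, idx)
            z = rng.standard_normal((config.n_timepoints, config.n_rois))
            values = z @ chol[g].T
            subjects.append(TimeSeriesMatrix(f"sub-{idx + 1:04d}", values, label))
            labels.append(label)
            idx += 1
    return subjects, np.asarray(labels)


def write_cohort(subjects: list[TimeSeriesMatrix], outdir: str | Path,
                 config: CohortConfig | None = None) -> Path:
    """Write one TSV per subject plus a manifest TSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        rel = f"{ts.subject_id}.tsv"
        np.savetxt(outdir / rel, ts.values, delimiter="\t", fmt="%.10g")
        rows.append({"subject_id": ts.subject_id, "label": ts.label, "path": rel,
                     "seed": "" if config is None else config.seed})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["labels"] = ",".join(config.labels)
        pd.Series(cfg).to_csv(outdir / "cohort_config.tsv", sep="\t", header=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> tuple[list[TimeSeriesMatrix], np.ndarray]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    subjects = []
    for row in table.itertuples():
        path = manifest_path.parent / row.path
        if not path.exists():
            raise FileNotFoundError(
                f"manifest row for subject {row.subject_id}: missing file {path}")
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        subjects.append(TimeSeriesMatrix(str(row.subject_id), values, str(row.label)))
    return subjects, table["label"].to_numpy(dtype=str)
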