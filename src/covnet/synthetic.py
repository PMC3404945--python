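"""Synthetic two-group cohorts of regional volumes with planted covariance structure.

Each group is drawn from a zero-mean multivariate normal whose correlation
matrix is block-constant: ROIs are partitioned into ``n_modules`` planted
communities with correlation ``r_within`` inside a module and ``r_between``
across modules.  Linear age and total-brain-volume (TBV) effects are added on
top, so the confound-regression stage downstream has something real to remove.
The two groups share module layout, marginal variance, and confound
coefficients; they may differ in within-module correlation strength, which is
what drives between-group clustering differences in the derived networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SubjectVolumeTable",
    "block_correlation_matrix",
    "module_assignments",
    "generate_cohort",
]

#: Age range (years) used for the uniform age covariate.
AGE_RANGE = (43.0, 67.0)
#: Mean / SD of the normal total-brain-volume covariate (arbitrary volume units).
TBV_MEAN = 1400.0
TBV_SD = 120.0

_PD_TOL = 1e-10


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Parameters
    ----------
    n_subjects_per_group:
        Number of subjects in each of the two groups.
    n_rois:
        Number of regions of interest (columns of the volume matrix).
    n_modules:
        Number of planted communities.  ROIs are split into equal-sized
        modules; any remainder is appended to the last module.
    r_within_a, r_within_b:
        Within-module correlation of the confound-free component for group A
        and group B respectively; each must lie in ``[0, 1)``.
    r_between:
        Cross-module correlation, identical for both groups; must be
        strictly smaller than both within-module values.
    beta_age, beta_tbv:
        Linear confound coefficients (volume units per covariate unit).
        Either scalars applied to all ROIs or length-``n_rois`` sequences.
    noise_sd:
        Marginal standard deviation of the confound-free component.
    seed:
        Seed for all randomness (covariates and volumes of both groups).
    roi_labels:
        Optional explicit ROI labels; defaults to ``ROI_001`` ... style names.
    """

    n_subjects_per_group: int
    n_rois: int = 90
    n_modules: int = 1
    r_within_a: float = 0.0
    r_within_b: float = 0.0
    r_between: float = 0.0
    beta_age: float | Sequence[float] = 0.0
    beta_tbv: float | Sequence[float] = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be a positive integer")
        if self.n_rois < 1:
            raise ValueError("n_rois must be a positive integer")
        if not 1 <= self.n_modules <= self.n_rois:
            raise ValueError("n_modules must be in [1, n_rois]")
        for name in ("r_within_a", "r_within_b"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name}={r} must lie in [0, 1)")
        r_min = min(self.r_within_a, self.r_within_b)
        if self.n_modules > 1 and not 0.0 <= self.r_between <= r_min:
            raise ValueError(
                f"r_between={self.r_between} must lie in [0, min(r_within)="
                f"{r_min}]"
            )
        if self.r_between > r_min:
            raise ValueError(
                f"r_between={self.r_between} exceeds min(r_within)={r_min}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.roi_labels is not None and len(self.roi_labels) != self.n_rois:
            raise ValueError(
                f"roi_labels has {len(self.roi_labels)} entries, expected "
                f"{self.n_rois}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        if self.roi_labels is not None:
            return tuple(self.roi_labels)
        width = max(3, len(str(self.n_rois)))
        return tuple(f"ROI_{i + 1:0{width}d}" for i in range(self.n_rois))


@dataclass
class SubjectVolumeTable:
    """Subjects-by-ROI volume matrix with per-subject covariates.

    ``covariates`` is a DataFrame whose rows align with ``subject_ids`` /
    rows of ``volumes`` (typically columns ``age`` and ``tbv``).
    """

    group_label: str
    subject_ids: list[str]
    roi_labels: list[str]
    volumes: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        n, p = self.volumes.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match volume rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(self.roi_labels) != p:
            raise ValueError("roi_labels length does not match volume columns")
        if len(set(self.roi_labels)) != p:
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.volumes)):
            raise ValueError("volumes contain non-finite values")
        if len(self.covariates) != n:
            raise ValueError("covariates rows do not match subjects")
        if not np.all(np.isfinite(self.covariates.to_numpy(dtype=float))):
            raise ValueError("covariates contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_rois(self) -> int:
        return self.volumes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk layout: subject_id, group, covariates, ROIs."""
        frame = pd.DataFrame({"subject_id": self.subject_ids, "group": self.group_label})
        for name in self.covariates.columns:
            frame[name] = np.asarray(self.covariates[name], dtype=float)
        vol = pd.DataFrame(self.volumes, columns=self.roi_labels, index=frame.index)
        return pd.concat([frame, vol], axis=1)


def module_assignments(n_rois: int, n_modules: int) -> np.ndarray:
    """Module index per ROI: equal-sized blocks, remainder on the last module."""
    base = n_rois // n_modules
    assign = np.repeat(np.arange(n_modules), base)
    remainder = n_rois - base * n_modules
    if remainder:
        assign = np.concatenate([assign, np.full(remainder, n_modules - 1)])
    return assign


def block_correlation_matrix(
    n_rois: int, n_modules: int, r_within: float, r_between: float
) -> np.ndarray:
    """Block-constant correlation matrix of the planted community model."""
    assign = module_assignments(n_rois, n_modules)
    same = assign[:, None] == assign[None, :]
    corr = np.where(same, r_within, r_between)
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_positive_definite(
    corr: np.ndarray, group: str, r_within: float, r_between: float, n_modules: int
) -> np.ndarray:
    smallest = float(np.linalg.eigvalsh(corr)[0])
    if smallest <= _PD_TOL:
        raise ValueError(
            f"correlation model for group {group} is not positive definite "
            f"(smallest eigenvalue {smallest:.3e}) with r_within={r_within}, "
            f"r_between={r_between}, n_modules={n_modules}"
        )
    return corr


def _per_roi(coef: float | Sequence[float], n_rois: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(coef, dtype=float), (n_rois,))
    if not np.all(np.isfinite(arr)):
        raise ValueError("confound coefficients must be finite")
    return arr


def generate_cohort(spec: CohortSpec) -> tuple[SubjectVolumeTable, SubjectVolumeTable]:
    """Draw the two group tables described by ``spec``.

    The confound-free component of group g is MVN(0, noise_sd**2 * C_g) with
    C_g the block-constant correlation matrix; ``beta_age * age + beta_tbv *
    tbv`` is then added to every ROI.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.labels)
    beta_age = _per_roi(spec.beta_age, spec.n_rois)
    beta_tbv = _per_roi(spec.beta_tbv, spec.n_rois)

    chols = {}
    for group, r_within in (("A", spec.r_within_a), ("B", spec.r_within_b)):
        corr = block_correlation_matrix(
            spec.n_rois, spec.n_modules, r_within, spec.r_between
        )
        _check_positive_definite(corr, group, r_within, spec.r_between, spec.n_modules)
        chols[group] = np.linalg.cholesky(corr)

    tables = []
    for group in ("A", "B"):
        n = spec.n_subjects_per_group
        age = rng.uniform(*AGE_RANGE, size=n)
        tbv = rng.normal(TBV_MEAN, TBV_SD, size=n)
        core = spec.noise_sd * rng.standard_normal((n, spec.n_rois)) @ chols[group].T
        volumes = core + np.outer(age, beta_age) + np.outer(tbv, beta_tbv)
        width = max(3, len(str(n)))
        tables.append(
            SubjectVolumeTable(
                group_label=group,
                subject_ids=[f"{group}{i + 1:0{width}d}" for i in range(n)],
                roi_labels=labels,
                volumes=volumes,
                covariates=pd.DataFrame({"age": age, "tbv": tbv}),
            )
        )
    return tables[0], tables[1]
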