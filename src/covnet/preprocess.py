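"""Per-ROI linear confound removal.

Each ROI column is regressed (ordinary least squares, intercept always
included) on the named per-subject covariates; the residuals replace the raw
volumes for all downstream network construction.
"""

from __future__ import annotations

import numpy as np

from .synthetic import SubjectVolumeTable

__all__ = ["ResidualTable", "regress_confounds", "regress_confounds_pooled"]

_COND_LIMIT = 1e10


class ResidualTable(SubjectVolumeTable):
    """A :class:`SubjectVolumeTable` whose values are OLS residuals."""


def _design_matrix(table: SubjectVolumeTable, covariate_names: list[str]) -> np.ndarray:
    missing = [c for c in covariate_names if c not in table.covariates.columns]
    if missing:
        raise ValueError(f"unknown covariates: {', '.join(missing)}")
    cols = [np.ones(table.n_subjects)]
    cols.extend(
        np.asarray(table.covariates[name], dtype=float) for name in covariate_names
    )
    return np.column_stack(cols)


def _check_design(design: np.ndarray, covariate_names: list[str]) -> None:
    n, p = design.shape
    if n < p + 1:
        raise ValueError(
            f"need at least {p + 1} subjects to fit {p - 1} covariates plus an "
            f"intercept, got {n}"
        )
    if np.linalg.matrix_rank(design) < p or np.linalg.cond(design) > _COND_LIMIT:
        # Identify which covariates are (near-)collinear with the rest.
        suspects = []
        for j, name in enumerate(covariate_names, start=1):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                suspects.append(name)
        raise ValueError(
            "rank-deficient confound design; collinear covariates: "
            + ", ".join(suspects or covariate_names)
        )


def _residualize(volumes: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, volumes, rcond=None)
    return volumes - design @ beta


def regress_confounds(
    table: SubjectVolumeTable, covariate_names: list[str] | tuple[str, ...] = ("age", "tbv")
) -> ResidualTable:
    """OLS-residualize every ROI on an intercept plus the named covariates.

    Raises ``ValueError`` for a rank-deficient design (naming the collinear
    covariates) or when there are fewer subjects than parameters plus one.
    """
    names = list(covariate_names)
    design = _design_matrix(table, names)
    _check_design(design, names)
    residuals = _residualize(table.volumes, design)
    return ResidualTable(
        group_label=table.group_label,
        subject_ids=list(table.subject_ids),
        roi_labels=list(table.roi_labels),
        volumes=residuals,
        covariates=table.covariates.copy(),
    )


def regress_confounds_pooled(
    table_a: SubjectVolumeTable,
    table_b: SubjectVolumeTable,
    covariate_names: list[str] | tuple[str, ...] = ("age", "tbv"),
) -> tuple[ResidualTable, ResidualTable]:
    """Fit one confound model on both groups jointly, then split the residuals.

    Used when the permutation pathway requires residuals computed once on the
    pooled sample rather than per group.
    """
    if table_a.roi_labels != table_b.roi_labels:
        raise ValueError("ROI labels differ between the two tables")
    names = list(covariate_names)
    design_a = _design_matrix(table_a, names)
    design_b = _design_matrix(table_b, names)
    design = np.vstack([design_a, design_b])
    _check_design(design, names)
    stacked = np.vstack([table_a.volumes, table_b.volumes])
    residuals = _residualize(stacked, design)
    n_a = table_a.n_subjects
    out = []
    for table, block in ((table_a, residuals[:n_a]), (table_b, residuals[n_a:])):
        out.append(
            ResidualTable(
                group_label=table.group_label,
                subject_ids=list(table.subject_ids),
                roi_labels=list(table.roi_labels),
                volumes=block,
                covariates=table.covariates.copy(),
            )
        )
    return out[0], out[1]
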