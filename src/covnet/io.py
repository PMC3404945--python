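"""Reading and writing the package's plain-text formats.

Volume/residual tables are CSV: subject_id, group, one column per covariate,
then one column per ROI.  Association matrices are labelled square CSVs.
Binary graphs are written both as adjacency CSV and as a three-column edge
list compatible with generic network viewers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .netbuild import AssociationMatrix, BinaryGraph
from .preprocess import ResidualTable
from .synthetic import SubjectVolumeTable

__all__ = [
    "read_volume_table",
    "write_volume_table",
    "read_association_matrix",
    "write_association_matrix",
    "write_graph",
    "load_aal90_labels",
]

RESERVED_COLUMNS = ("subject_id", "group")
DEFAULT_COVARIATES = ("age", "tbv")

_FLOAT_FORMAT = "%.12g"


def read_volume_table(
    path: str | Path,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    *,
    residuals: bool = False,
) -> SubjectVolumeTable:
    """Parse and validate a subject-by-ROI CSV.

    The file must contain ``subject_id`` and ``group`` columns, every named
    covariate, and at least two ROI columns; the single ``group`` value
    becomes the table's label.  Errors name the offending row/column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    for col in RESERVED_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate column(s) {', '.join(missing)}")
    roi_labels = [
        c for c in frame.columns if c not in RESERVED_COLUMNS and c not in covariates
    ]
    if len(roi_labels) < 2:
        raise ValueError(f"{path}: need at least 2 ROI columns, found {len(roi_labels)}")
    dup = frame["subject_id"][frame["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    groups = frame["group"].unique()
    if len(groups) != 1:
        raise ValueError(
            f"{path}: expected a single group per file, found {sorted(groups)}"
        )
    numeric_cols = list(covariates) + roi_labels
    for col in numeric_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{path}: missing or non-numeric value in column {col!r}, "
                f"row {row} (subject {frame['subject_id'].iloc[row]})"
            )
        frame[col] = values.astype(float)
    cls = ResidualTable if residuals else SubjectVolumeTable
    return cls(
        group_label=str(groups[0]),
        subject_ids=frame["subject_id"].tolist(),
        roi_labels=roi_labels,
        volumes=frame[roi_labels].to_numpy(dtype=float),
        covariates=frame[list(covariates)].reset_index(drop=True),
    )


def write_volume_table(table: SubjectVolumeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_association_matrix(assoc: AssociationMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(assoc.values, index=assoc.roi_labels, columns=assoc.roi_labels)
    frame.to_csv(path, index_label="roi", float_format=_FLOAT_FORMAT)


def read_association_matrix(path: str | Path, n_subjects: int = 0) -> AssociationMatrix:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: association matrix rows/columns do not match")
    return AssociationMatrix(
        roi_labels=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        n_subjects=n_subjects,
    )


def write_graph(
    graph: BinaryGraph, adjacency_path: str | Path, edgelist_path: str | Path | None = None
) -> None:
    frame = pd.DataFrame(
        graph.adjacency, index=graph.roi_labels, columns=graph.roi_labels
    )
    frame.to_csv(adjacency_path, index_label="roi")
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            fh.write("roi_i\troi_j\tweight\n")
            for a, b in graph.edge_list():
                fh.write(f"{a}\t{b}\t1\n")


def load_aal90_labels() -> list[str]:
    """The packaged 90-region label list (45 bilateral regions, cerebellum excluded)."""
    text = resources.files("covnet.data").joinpath("aal90_labels.txt").read_text()
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    if len(labels) != 90:
        raise RuntimeError(f"packaged label fixture has {len(labels)} entries, expected 90")
    return labels
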