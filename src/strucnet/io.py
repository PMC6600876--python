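"""Delimited-text readers and writers for every interchange object.

All interchange is plain comma-separated text so fixtures stay diffable:
labeled square matrices (header row + label column), a parcellation
table, a cohort manifest, two-column expression tables and long-format
donor tables. A matrix read back is realigned to the reference label
order if the file permutes it.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .netgen import (
    Cohort,
    ExpressionProfile,
    Parcellation,
    Region,
    Subject,
    SubjectPair,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_parcellation",
    "write_parcellation",
    "read_expression",
    "write_expression",
    "read_donor_expression",
    "write_cohort",
    "read_cohort",
]

_SYMMETRY_TOL = 1e-9


def write_matrix(
    matrix: np.ndarray, labels: Sequence[str], path: str | os.PathLike
) -> None:
    """Write a labeled square matrix as CSV (header row + label column)."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match {n} labels"
        )
    frame = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    frame.to_csv(path, float_format="%.17g")


def read_matrix(
    path: str | os.PathLike, labels: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Read a labeled square matrix; validate symmetry; realign to labels.

    Returns ``(labels, matrix)``. If a reference label order is given,
    the matrix is permuted to that order; unknown or missing labels are
    a label-mismatch error. Asymmetric entries (beyond 1e-9) and
    non-numeric cells are distinct diagnostics naming the offending
    cell.
    """
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except ValueError as err:
        raise ValidationError(f"{path}: unreadable matrix ({err})") from err
    file_labels = [str(x) for x in frame.index]
    if [str(c) for c in frame.columns] != file_labels:
        raise ValidationError(f"{path}: row and column labels differ")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            cell = f"({bad[0]!r}, {col!r})" if len(bad) else f"column {col!r}"
            raise ValidationError(f"{path}: non-numeric cell at {cell}")
    matrix = frame.to_numpy(dtype=float)
    asym = np.abs(matrix - matrix.T)
    if asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"{path}: asymmetric entry at ({file_labels[i]!r}, "
            f"{file_labels[j]!r}): {matrix[i, j]!r} vs {matrix[j, i]!r}"
        )
    if labels is not None:
        want = [str(x) for x in labels]
        if set(want) != set(file_labels):
            raise ValidationError(
                f"{path}: labels do not match the reference parcellation"
            )
        if want != file_labels:
            idx = [file_labels.index(lab) for lab in want]
            matrix = matrix[np.ix_(idx, idx)]
            file_labels = want
    return file_labels, matrix


def write_parcellation(
    parcellation: Parcellation, path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "label": parcellation.labels,
            "hemisphere": [r.hemisphere for r in parcellation.regions],
            "tissue": [r.tissue for r in parcellation.regions],
        }
    ).to_csv(path, index=False)


def read_parcellation(path: str | os.PathLike) -> Parcellation:
    frame = pd.read_csv(path)
    required = {"label", "hemisphere", "tissue"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    return Parcellation(
        tuple(
            Region(row.label, row.hemisphere, row.tissue)
            for row in frame.itertuples()
        )
    )


def write_expression(
    profile: ExpressionProfile, path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {"region": profile.labels, "value": profile.values}
    ).to_csv(path, index=False)


def read_expression(
    path: str | os.PathLike, gene: str | None = None
) -> ExpressionProfile:
    frame = pd.read_csv(path)
    if not {"region", "value"} <= set(frame.columns):
        raise ValidationError(f"{path}: needs columns ['region', 'value']")
    return ExpressionProfile(
        gene=gene or Path(path).stem,
        labels=tuple(str(x) for x in frame["region"]),
        values=frame["value"].to_numpy(dtype=float),
    )


def read_donor_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Long-format donor table with columns donor, region, value."""
    frame = pd.read_csv(path)
    if not {"donor", "region", "value"} <= set(frame.columns):
        raise ValidationError(
            f"{path}: needs columns ['donor', 'region', 'value']"
        )
    return frame


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> None:
    """Write a cohort as one counts + one FA matrix per subject, a
    manifest, and the parcellation table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = cohort.parcellation.labels
    write_parcellation(cohort.parcellation, out / "parcellation.csv")
    manifest_rows = []
    for pair_id, pair in enumerate(cohort.pairs):
        for group, subj in (("case", pair.case), ("control", pair.control)):
            write_matrix(
                subj.count_matrix, labels, out / f"{subj.subject_id}_counts.csv"
            )
            write_matrix(
                subj.fa_matrix, labels, out / f"{subj.subject_id}_fa.csv"
            )
            manifest_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": group,
                    "pair_id": pair_id,
                    "age": subj.age,
                }
            )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)


def read_cohort(in_dir: str | os.PathLike) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    parcellation = read_parcellation(root / "parcellation.csv")
    manifest = pd.read_csv(root / "manifest.csv")
    required = {"subject_id", "group", "pair_id", "age"}
    if not required <= set(manifest.columns):
        raise ValidationError(
            f"{root / 'manifest.csv'}: needs columns {sorted(required)}"
        )
    labels = parcellation.labels

    def load_subject(row) -> Subject:
        _, counts = read_matrix(
            root / f"{row.subject_id}_counts.csv", labels
        )
        _, fa = read_matrix(root / f"{row.subject_id}_fa.csv", labels)
        return Subject(str(row.subject_id), float(row.age), counts, fa)

    pairs = []
    for pair_id, block in manifest.groupby("pair_id"):
        by_group = {row.group: load_subject(row) for row in block.itertuples()}
        if set(by_group) != {"case", "control"}:
            raise ValidationError(
                f"pair {pair_id} must have exactly one case and one control"
            )
        pairs.append(
            SubjectPair(case=by_group["case"], control=by_group["control"])
        )
    cohort = Cohort(pairs=tuple(pairs), parcellation=parcellation)
    cohort.validate()
    return cohort
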