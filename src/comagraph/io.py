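"""Delimited-text I/O for time series, matrices and cohort tables.

The pipeline's boundary is parcellated node time series: one tab-delimited
table per subject (nodes as rows, a header row of volume indices, a
``node`` index column), plus a cohort metadata CSV.  No imaging formats.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SubjectRecord, cohort_metadata_frame

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "write_cohort",
    "read_metadata",
    "write_matrix",
    "read_matrix",
]


def read_subject_table(path) -> tuple[np.ndarray, dict]:
    """Parse a nodes x volumes table; return (array, validation report).

    Raises ``ValueError`` with row/column coordinates for non-numeric
    cells, ragged rows, or duplicate node identifiers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path.name}: ragged or malformed table: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate node id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path.name}: non-numeric cell at node {row!r}, volume {col!r}"
            )
        df[col] = coerced
    arr = df.to_numpy(dtype=float)
    report = {
        "n_nodes": arr.shape[0],
        "n_volumes": arr.shape[1],
        "n_missing": int(np.isnan(arr).sum()),
    }
    return arr, report


def write_subject_table(path, timeseries: np.ndarray) -> None:
    """Write nodes x volumes as TSV with volume-index header and node ids."""
    ts = np.asarray(timeseries, dtype=float)
    df = pd.DataFrame(
        ts,
        index=pd.Index([f"node{i}" for i in range(ts.shape[0])], name="node"),
        columns=[str(j) for j in range(ts.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_cohort(records: list[SubjectRecord], outdir) -> Path:
    """One TSV per subject plus a metadata CSV; returns the metadata path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records:
        write_subject_table(outdir / f"{r.subject_id}_timeseries.tsv", r.timeseries)
    meta_path = outdir / "metadata.csv"
    cohort_metadata_frame(records).to_csv(meta_path, index=False)
    return meta_path


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"subject_id", "outcome", "eeg_category", "eeg_class",
                "pupils_ssep_absent", "arrest_to_mri_hours", "hospital",
                "comatose_during_mri"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.8f")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
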