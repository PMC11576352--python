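"""Canonical TSV dialects for the spectral matrix and the annotation table.

Matrix layout: one header row ``sample_id`` followed by the ppm values
(printed with ``repr`` so doubles round-trip exactly), then one row per
sample.  Lines starting with ``#`` before the header are comments.  All text
is UTF-8; the decimal separator is ``.``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..types import AnnotationTable, SpectraMatrix

__all__ = ["read_tsv_matrix", "write_tsv_matrix",
           "read_annotations", "write_annotations"]


def write_tsv_matrix(matrix: SpectraMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(repr(float(v)) for v in matrix.ppm_grid)
                 + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.X):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_tsv_matrix(path: str | Path) -> SpectraMatrix:
    path = Path(path)
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if header is None and (not line or line.startswith("#")):
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0] != "sample_id":
                    raise ValueError(
                        f"{path}: header must start with 'sample_id', "
                        f"got {cells[0]!r}")
                header = cells
                continue
            if not line:
                continue
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} cells, "
                    f"header has {len(header)}")
            sid = cells[0]
            if sid in sample_ids:
                raise ValueError(f"{path}: duplicate sample id {sid!r} "
                                 f"at row {lineno}")
            values = np.empty(len(cells) - 1)
            for j, cell in enumerate(cells[1:], start=2):
                try:
                    values[j - 2] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {lineno}, "
                        f"column {j}: {cell!r}") from None
            sample_ids.append(sid)
            rows.append(values)
    if header is None:
        raise ValueError(f"{path}: no header row found")
    ppm = np.array([float(v) for v in header[1:]])
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    return SpectraMatrix(sample_ids, ppm, np.vstack(rows))


def read_annotations(path: str | Path) -> AnnotationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    df = df.set_index("sample_id")
    return AnnotationTable(df)


def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    df = annotations.table.reset_index()
    df = df.rename(columns={df.columns[0]: "sample_id"})
    df.to_csv(Path(path), sep="\t", index=False)
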