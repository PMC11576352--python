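"""Spectral input/output: JCAMP-DX, Bruker processed directories, TSV.

Heterogeneous spectra are brought onto a shared descending ppm grid with
:func:`align_to_grid` before any statistics are computed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from ..types import AnnotationTable, SpectraMatrix, Spectrum
from .bruker import read_bruker, write_bruker
from .jcamp import read_jcamp, write_jcamp
from .tsv import (read_annotations, read_tsv_matrix, write_annotations,
                  write_tsv_matrix)

__all__ = [
    "read_jcamp", "write_jcamp", "read_bruker", "write_bruker",
    "read_tsv_matrix", "write_tsv_matrix", "read_annotations",
    "write_annotations", "align_to_grid", "load_spectra",
]

logger = logging.getLogger("nmrprofile.io")


def align_to_grid(spectra: list[Spectrum], grid: np.ndarray, *,
                  out_of_range: str = "zero-fill") -> SpectraMatrix:
    """Linearly interpolate each spectrum onto a common descending grid.

    Grid points outside a spectrum's ppm range are filled with 0 under the
    default ``zero-fill`` policy (a warning is logged); with
    ``out_of_range="error"`` such spectra raise instead.  Extrapolation is
    never performed.
    """
    if not spectra:
        raise ValueError("no spectra to align")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) < 0):
        raise ValueError("grid must be strictly descending")
    rows = np.zeros((len(spectra), len(grid)))
    ids: list[str] = []
    for i, spec in enumerate(spectra):
        lo, hi = spec.ppm[-1], spec.ppm[0]  # stored descending
        outside = (grid > hi) | (grid < lo)
        if outside.any():
            if out_of_range == "error":
                raise ValueError(
                    f"spectrum {spec.sample_id!r} ({lo}..{hi} ppm) does not "
                    f"cover the grid ({grid[-1]}..{grid[0]} ppm)")
            logger.warning("%s: %d grid points outside spectral range, "
                           "zero-filled", spec.sample_id, int(outside.sum()))
        # np.interp wants ascending abscissae
        rows[i] = np.interp(grid[::-1], spec.ppm[::-1], spec.intensity[::-1],
                            left=0.0, right=0.0)[::-1]
        rows[i, outside] = 0.0
        ids.append(spec.sample_id)
    ids = _dedupe_ids(ids)
    return SpectraMatrix(ids, grid, rows)


def _dedupe_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out: list[str] = []
    for sid in ids:
        if sid in seen:
            seen[sid] += 1
            new = f"{sid}_{seen[sid]}"
            logger.warning("duplicate sample id %r renamed to %r", sid, new)
            out.append(new)
        else:
            seen[sid] = 0
            out.append(sid)
    return out


def load_spectra(paths: list[str | Path]) -> list[Spectrum]:
    """Read a mixed list of JCAMP files and Bruker directories.

    Sample ids default to the file/directory basename; collisions get a
    numeric suffix with a logged warning.
    """
    spectra = []
    for p in paths:
        p = Path(p)
        spectra.append(read_bruker(p) if p.is_dir() else read_jcamp(p))
    ids = _dedupe_ids([s.sample_id for s in spectra])
    for spec, sid in zip(spectra, ids):
        spec.sample_id = sid
    return spectra
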