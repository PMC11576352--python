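"""Reader for Bruker processed-data directories (``procs`` + ``1r``).

A processed 1D dataset stores its real spectrum as int32 values in ``1r``
and the axis/scaling metadata in the ``procs`` parameter file.  Intensities
are ``1r`` values times ``2**NC_proc``; the ppm axis runs from ``OFFSET``
down across a spectral width of ``SW_p / SF`` ppm over ``SI`` points.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from ..types import Spectrum

__all__ = ["read_bruker", "write_bruker", "BrukerParseError",
           "BrukerIntegrityError"]

REQUIRED_KEYS = ("OFFSET", "SW_p", "SF", "SI", "BYTORDP", "NC_proc")


class BrukerParseError(ValueError):
    pass


class BrukerIntegrityError(ValueError):
    pass


_PARAM = re.compile(r"^##\$(\w+)=\s*(.*)$")


def _read_procs(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        m = _PARAM.match(line.strip())
        if m:
            params[m.group(1)] = m.group(2).strip()
    return params


def read_bruker(directory: str | Path) -> Spectrum:
    """Read a processed Bruker directory into a :class:`Spectrum`."""
    directory = Path(directory)
    procs_path = directory / "procs"
    data_path = directory / "1r"
    if not procs_path.exists():
        raise BrukerParseError(f"no procs file in {directory}")
    if not data_path.exists():
        raise BrukerParseError(f"no 1r file in {directory}")

    params = _read_procs(procs_path)
    missing = [k for k in REQUIRED_KEYS if k not in params]
    if missing:
        raise BrukerParseError(f"procs missing required keys: {missing}")

    si = int(float(params["SI"]))
    offset = float(params["OFFSET"])
    sw_ppm = float(params["SW_p"]) / float(params["SF"])
    nc_proc = int(float(params["NC_proc"]))
    big_endian = int(float(params["BYTORDP"])) == 1

    raw = data_path.read_bytes()
    if len(raw) != 4 * si:
        raise BrukerIntegrityError(
            f"1r holds {len(raw)} bytes, expected 4*SI = {4 * si}")
    dtype = ">i4" if big_endian else "<i4"
    ints = np.frombuffer(raw, dtype=dtype)
    intensity = ints.astype(float) * 2.0 ** nc_proc
    ppm = np.linspace(offset, offset - sw_ppm, si)
    return Spectrum(sample_id=directory.name, ppm=ppm, intensity=intensity,
                    meta={"source": str(directory),
                          "frequency_mhz": params["SF"]})


def write_bruker(directory: str | Path, intensities: np.ndarray, *,
                 offset: float, sw_p: float, sf: float,
                 bytordp: int = 0, nc_proc: int = 0) -> None:
    """Write a minimal processed directory (fixture/export helper).

    *intensities* are divided by ``2**nc_proc`` and rounded to int32.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    si = len(intensities)
    ints = np.rint(np.asarray(intensities, float) / 2.0 ** nc_proc)
    if np.any(np.abs(ints) > np.iinfo(np.int32).max):
        raise ValueError("intensities overflow int32 at this NC_proc")
    dtype = ">i4" if bytordp == 1 else "<i4"
    (directory / "1r").write_bytes(ints.astype(dtype).tobytes())
    procs = "\n".join([
        "##TITLE= Parameter file, TopSpin-compatible subset",
        f"##$BYTORDP= {bytordp}",
        f"##$NC_proc= {nc_proc}",
        f"##$OFFSET= {float(offset)!r}",
        f"##$SF= {float(sf)!r}",
        f"##$SI= {si}",
        f"##$SW_p= {float(sw_p)!r}",
        "##END=",
    ])
    (directory / "procs").write_text(procs + "\n", encoding="utf-8")
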