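"""JCAMP-DX single-spectrum reader and writer.

Covers the dialect commonly produced by Bruker export tools: an
``##XYDATA= (X++(Y..Y))`` block with AFFN (plain numbers) or ASDF-compressed
ordinates in the SQZ / DIF / DUP forms.  PAC packing and NTUPLES records are
rejected with an explicit message.  The writer exists so compressed fixtures
can be generated and round-tripped in tests and by the simulator export.

ASDF pseudo-digits (JCAMP-DX 4.24):

========  ======================================  =================
form      positive / zero                          negative
========  ======================================  =================
SQZ       ``@`` (0), ``A``-``I`` (1-9)            ``a``-``i``
DIF       ``%`` (0), ``J``-``R`` (1-9)            ``j``-``r``
DUP       ``S``-``Z`` (1-8), ``s`` (9)            --
========  ======================================  =================

A SQZ token starts a new ordinate value; a DIF token adds a difference to
the previous value; a DUP token repeats the previous token.  In DIF mode
every continuation line starts with an X value followed by a *check* copy of
the previous line's last ordinate, which is validated and dropped.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from ..types import Spectrum

__all__ = ["read_jcamp", "write_jcamp", "JcampParseError", "JcampIntegrityError"]


class JcampParseError(ValueError):
    """Structural problem: missing label or unsupported dialect."""


class JcampIntegrityError(ValueError):
    """Decoded data contradicts the file's own metadata."""


_SQZ = {"@": 0, **{chr(ord("A") + i): i + 1 for i in range(9)},
        **{chr(ord("a") + i): -(i + 1) for i in range(9)}}
_DIF = {"%": 0, **{chr(ord("J") + i): i + 1 for i in range(9)},
        **{chr(ord("j") + i): -(i + 1) for i in range(9)}}
_DUP = {**{chr(ord("S") + i): i + 1 for i in range(8)}, "s": 9}

_TOKEN = re.compile(
    r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"   # AFFN number
    r"|[@A-Ia-i%J-Rj-r][0-9]*"                     # SQZ / DIF start digit
    r"|[S-Zs][0-9]*"                               # DUP count
)


def _decode_pseudo(token: str, table: dict[str, int]) -> int:
    head = table[token[0]]
    rest = token[1:]
    if not rest:
        return head
    value = abs(head) * 10 ** len(rest) + int(rest)
    return -value if head < 0 else value


def _parse_labels(text: str) -> tuple[dict[str, str], str, int]:
    """Return (label -> value), the XYDATA variable list and its line index."""
    labels: dict[str, str] = {}
    lines = text.splitlines()
    xydata_line = -1
    xydata_var = ""
    for i, line in enumerate(lines):
        if not line.startswith("##"):
            continue
        key, _, value = line[2:].partition("=")
        key = key.strip().upper().replace(" ", "")
        value = value.strip()
        if key == "XYDATA":
            xydata_line = i
            xydata_var = value
            break
        labels[key] = value
    return labels, xydata_var, xydata_line


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a 1D JCAMP-DX file into a :class:`Spectrum`.

    The ppm axis is reconstructed as ``NPOINTS`` evenly spaced values from
    ``FIRSTX`` to ``LASTX``; ordinates are multiplied by ``YFACTOR``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    labels, xydata_var, xydata_line = _parse_labels(text)

    if "NTUPLES" in labels:
        raise JcampParseError("NTUPLES records are not supported; "
                              "export a single-spectrum (X++(Y..Y)) file")
    if xydata_line < 0:
        raise JcampParseError("missing required label ##XYDATA")
    var = xydata_var.replace(" ", "")
    if var != "(X++(Y..Y))":
        raise JcampParseError(
            f"unsupported XYDATA variable list {xydata_var!r}; only "
            "(X++(Y..Y)) is handled (PAC/XY pairs are out of scope)")
    for required in ("NPOINTS", "FIRSTX", "LASTX"):
        if required not in labels:
            raise JcampParseError(f"missing required label ##{required}")

    npoints = int(float(labels["NPOINTS"]))
    firstx = float(labels["FIRSTX"])
    lastx = float(labels["LASTX"])
    yfactor = float(labels.get("YFACTOR", "1"))

    ordinates: list[float] = []
    in_dif = False  # last decoded token of previous line was DIF/DUP-of-DIF
    for raw in text.splitlines()[xydata_line + 1:]:
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            break  # ##END= or next record
        tokens = _TOKEN.findall(line.partition("$$")[0])
        if not tokens:
            continue
        # first token on a data line is the abscissa
        line_has_check = in_dif
        last_mode = "affn"
        last_dif = 0
        first_y = True
        for tok in tokens[1:]:
            c = tok[0]
            if c in _DUP:
                count = _decode_pseudo(tok, _DUP)
                if not ordinates:
                    raise JcampParseError("DUP token with no preceding value")
                for _ in range(count - 1):
                    if last_mode == "dif":
                        ordinates.append(ordinates[-1] + last_dif)
                    else:
                        ordinates.append(ordinates[-1])
            elif c in _DIF:
                last_dif = _decode_pseudo(tok, _DIF)
                if not ordinates:
                    raise JcampParseError("DIF token with no starting value")
                ordinates.append(ordinates[-1] + last_dif)
                last_mode = "dif"
            else:
                value = (float(_decode_pseudo(tok, _SQZ)) if c in _SQZ
                         else float(tok))
                if first_y and line_has_check:
                    if abs(value - ordinates[-1]) > 1e-9 * max(
                            1.0, abs(ordinates[-1])):
                        raise JcampIntegrityError(
                            f"DIF check value {value} != previous line's "
                            f"last ordinate {ordinates[-1]}")
                else:
                    ordinates.append(value)
                last_mode = "affn"
            first_y = False
        in_dif = last_mode == "dif"

    if len(ordinates) != npoints:
        raise JcampIntegrityError(
            f"NPOINTS={npoints} but decoded {len(ordinates)} ordinates")

    ppm = np.linspace(firstx, lastx, npoints)
    intensity = np.asarray(ordinates, dtype=float) * yfactor
    meta = {"source": str(path)}
    if ".OBSERVEFREQUENCY" in labels:
        meta["frequency_mhz"] = labels[".OBSERVEFREQUENCY"]
    return Spectrum(sample_id=path.stem, ppm=ppm, intensity=intensity,
                    meta=meta)


def _encode_pseudo(value: int, table_pos: str, table_neg: str,
                   zero: str) -> str:
    digits = str(abs(value))
    if value == 0:
        return zero + digits[1:]
    head = int(digits[0])
    letter = table_pos[head - 1] if value > 0 else table_neg[head - 1]
    return letter + digits[1:]


def _sqz(v: int) -> str:
    return _encode_pseudo(v, "ABCDEFGHI", "abcdefghi", "@")


def _dif(v: int) -> str:
    return _encode_pseudo(v, "JKLMNOPQR", "jklmnopqr", "%")


def _dup(count: int) -> str:
    digits = str(count)
    return "STUVWXYZs"[int(digits[0]) - 1] + digits[1:]


def write_jcamp(spectrum: Spectrum, path: str | Path, *,
                compressed: bool = False, yfactor: float | None = None,
                line_width: int = 70) -> None:
    """Write a :class:`Spectrum` as JCAMP-DX.

    ``compressed=False`` emits AFFN ordinates; ``compressed=True`` emits the
    SQZ/DIF/DUP form (ordinates are divided by *yfactor* and rounded to
    integers, so choose a yfactor small enough for the wanted precision).
    """
    path = Path(path)
    n = len(spectrum)
    yf = 1.0 if yfactor is None else float(yfactor)
    firstx, lastx = float(spectrum.ppm[0]), float(spectrum.ppm[-1])
    header = [
        f"##TITLE= {spectrum.sample_id}",
        "##JCAMP-DX= 5.01",
        "##DATA TYPE= NMR SPECTRUM",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY UNITS",
        f"##NPOINTS= {n}",
        f"##FIRSTX= {firstx!r}",
        f"##LASTX= {lastx!r}",
        "##XFACTOR= 1",
        f"##YFACTOR= {yf!r}",
        f"##FIRSTY= {float(spectrum.intensity[0])!r}",
    ]
    lines = list(header)
    xstep = (lastx - firstx) / (n - 1)
    if not compressed:
        lines.append("##XYDATA= (X++(Y..Y))")
        i = 0
        while i < n:
            chunk = [f"{firstx + i * xstep:.6f}"]
            while i < n and len("  ".join(chunk)) < line_width:
                chunk.append(repr(float(spectrum.intensity[i] / yf)))
                i += 1
            lines.append(" ".join(chunk))
    else:
        ints = np.rint(spectrum.intensity / yf).astype(np.int64)
        lines.append("##XYDATA= (X++(Y..Y))")
        i = 0
        while i < n:
            start = i
            parts = [f"{firstx + i * xstep:.6f}", _sqz(int(ints[i]))]
            if start > 0:
                # DIF continuation: line starts with a check ordinate
                parts = [f"{firstx + i * xstep:.6f}", _sqz(int(ints[i]))]
            i += 1
            while i < n and len("".join(parts)) < line_width:
                d = int(ints[i] - ints[i - 1])
                run = 1
                while (i + run < n
                       and int(ints[i + run] - ints[i + run - 1]) == d
                       and len("".join(parts)) < line_width):
                    run += 1
                parts.append(_dif(d))
                if run > 1:
                    parts.append(_dup(run))
                i += run
            lines.append("".join(parts))
            if i < n:
                i -= 1  # repeat last ordinate as next line's check value
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
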