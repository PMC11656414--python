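"""Minimal JCAMP-DX reader for single 1D spectra.

Covers the plain tabular cases only: ``##XYDATA=(X++(Y..Y))`` blocks in
AFFN (free-form numeric) encoding, and ``##XYPOINTS=(XY..XY)`` pair lists.
The compressed ASCII schemes (PAC/SQZ/DIF/DUP) used by some vendors are not
handled — export uncompressed, or go through the delimited-matrix format,
which is the package's canonical interchange form.
"""

from __future__ import annotations

import re

import numpy as np

from .spectral import PpmAxis, Spectrum, ValidationError

__all__ = ["read_jcamp"]

_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _headers(lines: list[str]) -> dict[str, str]:
    out = {}
    for ln in lines:
        if ln.startswith("##"):
            key, _, val = ln[2:].partition("=")
            out[key.strip().upper()] = val.strip()
    return out


def read_jcamp(path, fraction_id: str | None = None) -> tuple[PpmAxis, Spectrum]:
    """Read one spectrum from a JCAMP-DX file (AFFN XYDATA or XYPOINTS)."""
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]
    hdr = _headers(lines)
    title = hdr.get("TITLE", "")
    fid = fraction_id or title or "jcamp"

    def block(tag: str) -> list[str] | None:
        start = None
        for i, ln in enumerate(lines):
            if ln.upper().startswith(f"##{tag}="):
                start = i
                break
        if start is None:
            return None
        body = []
        for ln in lines[start + 1 :]:
            if ln.startswith("##"):
                break
            body.append(ln)
        return body

    xfac = float(hdr.get("XFACTOR", "1") or 1)
    yfac = float(hdr.get("YFACTOR", "1") or 1)

    body = block("XYDATA")
    if body is not None:
        joined = re.sub(r"[eE][+-]?\d+", "", "".join(body))
        if re.search(r"[@A-DF-Za-df-z%]", joined):  # SQZ/DIF/DUP digit letters
            raise ValidationError(
                "compressed JCAMP-DX encodings are not supported; "
                "export AFFN (X++(Y..Y)) or use the delimited matrix format"
            )
        xs, ys = [], []
        for ln in body:
            nums = [float(t) for t in _NUM.findall(ln)]
            if len(nums) < 2:
                continue
            x0, yvals = nums[0], nums[1:]
            xs.append(x0)
            ys.append(yvals)
        if not ys:
            raise ValidationError("empty XYDATA block")
        npts = int(float(hdr.get("NPOINTS", sum(len(v) for v in ys))))
        first_x = float(hdr.get("FIRSTX", xs[0] * xfac)) if hdr.get("FIRSTX") else xs[0] * xfac
        last_x = float(hdr["LASTX"]) if hdr.get("LASTX") else None
        y = np.concatenate([np.asarray(v) for v in ys]) * yfac
        if npts != y.size:
            raise ValidationError(
                f"NPOINTS={npts} but {y.size} ordinates were read"
            )
        if last_x is None:
            # reconstruct spacing from per-line X checkpoints
            last_x = xs[-1] * xfac
            if len(ys) > 1 and y.size > len(ys[-1]):
                step = (xs[-1] - xs[0]) * xfac / (y.size - len(ys[-1]))
                last_x = first_x + step * (y.size - 1)
        x = np.linspace(first_x, last_x, y.size)
        return PpmAxis(x), Spectrum(fid, y)

    body = block("XYPOINTS")
    if body is None:
        body = block("PEAK TABLE")
    if body is not None:
        pts = [float(t) for ln in body for t in _NUM.findall(ln)]
        if len(pts) < 4 or len(pts) % 2:
            raise ValidationError("malformed XYPOINTS block")
        arr = np.asarray(pts).reshape(-1, 2)
        return PpmAxis(arr[:, 0] * xfac), Spectrum(fid, arr[:, 1] * yfac)

    raise ValidationError("no XYDATA or XYPOINTS block found")
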