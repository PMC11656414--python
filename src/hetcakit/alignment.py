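"""Segment-wise peak alignment of fraction spectra.

Small, concentration- and pH-dependent chemical-shift changes displace the
resonances of ionizable compounds between fractions, which scrambles
point-wise (and fine-bucket) correlation.  This module corrects them with a
rigid, segment-wise shift: the ppm axis is cut into fixed-width segments and,
for each segment, the integer-point shift within ``±max_shift`` that
maximizes the cross-correlation of the *first differences* of target and
reference is applied to the target's segment.  Points vacated at segment
edges are filled by linear interpolation between the surviving boundary
values, so intensity leakage is bounded and local.

Two reference policies exist.  ``pairwise-sequential`` (the default) aligns
spectrum k against the already-aligned spectrum k−1 in elution order — each
newly aligned spectrum becomes the "active" reference for the next.  This is
preferred over a single global reference because different compounds can
resonate at similar chemical shifts while living in different fractions;
neighboring fractions share composition, a distant reference may not.
``fixed-reference`` aligns everything to one chosen spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import PpmAxis, Spectrum, SpectrumSet, ValidationError

__all__ = ["AlignmentPlan", "AlignmentResult", "align_pair", "align_set"]


@dataclass(frozen=True)
class AlignmentPlan:
    """Parameters of segment-wise alignment.

    segment_width : ppm extent of each rigid segment (default 0.10 ppm).
    max_shift     : largest allowed displacement (default 0.02 ppm);
                    must not exceed half the segment width.
    reference_policy : "pairwise-sequential" or "fixed-reference".
    reference_index  : index of the reference spectrum in fixed mode.
    """

    segment_width: float = 0.10
    max_shift: float = 0.02
    reference_policy: str = "pairwise-sequential"
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.segment_width <= 0:
            raise ValidationError("segment_width must be positive")
        if not 0 < self.max_shift <= self.segment_width / 2:
            raise ValidationError("max_shift must lie in (0, segment_width/2]")
        if self.reference_policy not in ("pairwise-sequential", "fixed-reference"):
            raise ValidationError(
                f"unknown reference policy {self.reference_policy!r}"
            )

    def segment_points(self, axis: PpmAxis) -> int:
        return max(1, int(round(self.segment_width / axis.resolution)))

    def max_shift_points(self, axis: PpmAxis) -> int:
        return max(1, int(round(self.max_shift / axis.resolution)))


@dataclass(frozen=True)
class AlignmentResult:
    """Aligned spectra plus the per-spectrum, per-segment shift bookkeeping."""

    aligned: SpectrumSet
    shifts: np.ndarray  # (n_spectra, n_segments) integer points
    segment_bounds: np.ndarray  # (n_segments, 2) point indices [start, stop)
    reference_chain: tuple[int, ...]  # reference index per spectrum (-1 = none)

    def shift_table(self) -> pd.DataFrame:
        """Long-form report: fraction_id, segment ppm range, shift in points."""
        ppm = self.aligned.axis.values
        rows = []
        for i, fid in enumerate(self.aligned.fraction_ids):
            for k, (a, b) in enumerate(self.segment_bounds):
                seg_ppm = ppm[a:b]
                rows.append(
                    {
                        "fraction_id": fid,
                        "segment_lo": float(seg_ppm.min()),
                        "segment_hi": float(seg_ppm.max()),
                        "shift_points": int(self.shifts[i, k]),
                    }
                )
        return pd.DataFrame(rows)


def _segment_bounds(n_points: int, seg_len: int) -> np.ndarray:
    starts = np.arange(0, n_points, seg_len)
    stops = np.minimum(starts + seg_len, n_points)
    return np.column_stack([starts, stops])


def _best_shift(d_ref: np.ndarray, d_tar: np.ndarray, max_shift: int) -> int:
    """Integer shift s in [-max_shift, max_shift] maximizing
    sum_i d_ref[i] * d_tar[i - s] over the within-segment overlap.

    Ties: the smaller |s| wins; a remaining tie goes to the negative shift.
    """
    m = d_ref.size
    full = np.correlate(d_ref, d_tar, mode="full")  # lag k-(m-1): d_tar shifted
    center = m - 1
    lo = max(-max_shift, -(m - 1))
    hi = min(max_shift, m - 1)
    lags = np.arange(lo, hi + 1)
    scores = full[center + lags]
    # deterministic tie-break: sort candidates by (-score, |lag|, lag)
    order = sorted(range(lags.size), key=lambda i: (-scores[i], abs(lags[i]), lags[i]))
    return int(lags[order[0]])


def _apply_shift(seg: np.ndarray, s: int, left_anchor: float, right_anchor: float) -> np.ndarray:
    """Rigidly move a segment by s points; fill vacated edge points linearly."""
    if s == 0:
        return seg.copy()
    out = np.empty_like(seg)
    if s > 0:
        out[s:] = seg[:-s]
        out[:s] = np.linspace(left_anchor, seg[0], s + 2)[1:-1]
    else:
        out[:s] = seg[-s:]
        out[s:] = np.linspace(seg[-1], right_anchor, -s + 2)[1:-1]
    return out


def align_pair(
    target: Spectrum,
    reference: Spectrum,
    plan: AlignmentPlan,
    axis: PpmAxis,
) -> tuple[Spectrum, np.ndarray]:
    """Align ``target`` to ``reference`` segment by segment.

    Returns the aligned spectrum (on the original axis) and the integer
    per-segment shifts.  Segments shorter than 3 points are skipped with a
    warning and a zero shift, since a first-difference cross-correlation is
    meaningless there.
    """
    n = len(axis)
    if target.intensities.size != n or reference.intensities.size != n:
        raise ValidationError("target/reference do not match the axis length")
    seg_len = plan.segment_points(axis)
    max_pts = plan.max_shift_points(axis)
    bounds = _segment_bounds(n, seg_len)
    shifts = np.zeros(bounds.shape[0], dtype=int)
    out = target.intensities.copy()
    for k, (a, b) in enumerate(bounds):
        if b - a < 3:
            warnings.warn(
                f"segment {k} has {b - a} points (< 3); skipped", stacklevel=2
            )
            continue
        d_ref = np.diff(reference.intensities[a:b])
        d_tar = np.diff(target.intensities[a:b])
        s = _best_shift(d_ref, d_tar, min(max_pts, b - a - 2))
        left = out[a - 1] if a > 0 else target.intensities[a]
        right = target.intensities[b] if b < n else target.intensities[b - 1]
        out[a:b] = _apply_shift(target.intensities[a:b], s, left, right)
        shifts[k] = s
    return Spectrum(target.fraction_id, out), shifts


def align_set(s: SpectrumSet, plan: AlignmentPlan = AlignmentPlan()) -> AlignmentResult:
    """Align a whole fraction series according to ``plan``.

    Pairwise-sequential mode leaves the first spectrum untouched and aligns
    each subsequent spectrum against its already-aligned predecessor, so
    corrections propagate down the elution order.  The result depends on
    that order: running the chain on a reversed series is a different (and
    equally valid) alignment, not an error.  Fixed-reference mode aligns
    every spectrum to ``plan.reference_index``.
    """
    if len(s) < 2:
        raise ValidationError("alignment needs at least two spectra")
    seg_len = plan.segment_points(s.axis)
    bounds = _segment_bounds(len(s.axis), seg_len)
    shifts = np.zeros((len(s), bounds.shape[0]), dtype=int)

    if plan.reference_policy == "pairwise-sequential":
        aligned: list[Spectrum] = [s.spectra[0]]
        chain = [-1]
        for k in range(1, len(s)):
            spec, sh = align_pair(s.spectra[k], aligned[k - 1], plan, s.axis)
            aligned.append(spec)
            shifts[k] = sh
            chain.append(k - 1)
    else:
        ref_idx = plan.reference_index
        if not 0 <= ref_idx < len(s):
            raise ValidationError(
                f"reference index {ref_idx} out of range for {len(s)} spectra"
            )
        reference = s.spectra[ref_idx]
        aligned = []
        chain = []
        for k in range(len(s)):
            if k == ref_idx:
                aligned.append(reference)
                chain.append(-1)
                continue
            spec, sh = align_pair(s.spectra[k], reference, plan, s.axis)
            aligned.append(spec)
            shifts[k] = sh
            chain.append(ref_idx)

    return AlignmentResult(
        aligned=SpectrumSet(s.axis, tuple(aligned)),
        shifts=shifts,
        segment_bounds=bounds,
        reference_chain=tuple(chain),
    )
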