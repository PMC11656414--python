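"""Compound-level detection calls from pseudospectra, and their scoring.

A pseudospectrum flags spectral variables, not compounds.  To tally
performance the way a dereplication study does, each library compound's
diagnostic peaks are looked up in the kept buckets and a three-way call is
made: *not-detected* (its peaks carry no signal above the covariance noise
floor), *predicted active* (enough of its buckets show high positive
correlation with activity) or *predicted inactive*.  The numeric decision
rule here is an explicit operationalization of what is normally done by
expert reading of the colored plot plus STOCSY; every call carries its
per-bucket evidence so a human can override it.

Scoring follows the bookkeeping of ground-truthed evaluation studies:
undetected compounds enter the denominator of the active-compound success
rate but are never counted as false positives or false negatives, because
they were never characterized in terms of their correlation to activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .correlation import CorrelationOptions, Pseudospectrum
from .simulate import GroundTruth, MixtureDesign
from .spectral import ActivityTable, ValidationError

__all__ = [
    "PeakLibrary",
    "CompoundCall",
    "DetectionReport",
    "detect_compounds",
    "score_detection",
    "concentration_activity_audit",
    "library_from_design",
    "exact_rate",
]

ACTIVE, INACTIVE, NOT_DETECTED = "active", "inactive", "not-detected"


@dataclass(frozen=True)
class PeakLibrary:
    """Reference peak list per compound, with true labels for evaluation."""

    compounds: dict[str, tuple[float, ...]]  # name -> diagnostic peak ppms
    true_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValidationError("peak library is empty")
        for name, peaks in self.compounds.items():
            if len(peaks) == 0:
                raise ValidationError(f"{name}: needs at least one diagnostic peak")


def library_from_design(design: MixtureDesign, truth: GroundTruth) -> PeakLibrary:
    """Build the reference library a standards study would have on hand."""
    return PeakLibrary(
        compounds={
            c.name: tuple(p for p, _, _ in c.peaks) for c in design.compounds
        },
        true_labels=dict(truth.active_labels),
    )


@dataclass
class CompoundCall:
    """One compound's prediction plus the bucket evidence behind it."""

    name: str
    predicted: str  # active | inactive | not-detected
    ambiguous: bool = False
    evidence: pd.DataFrame | None = None  # peak_ppm, bucket_ppm, covariance, r


@dataclass
class DetectionReport:
    """Per-compound calls plus (after scoring) the aggregate tallies."""

    calls: dict[str, CompoundCall]
    high_corr_threshold: float
    low_corr_threshold: float
    min_peak_fraction: float
    noise_floor: float
    # filled by score_detection
    n_identified: int | None = None
    n_correct: int | None = None
    false_positives: int | None = None
    false_negatives: int | None = None
    n_true_active: int | None = None
    n_correct_active: int | None = None
    success_rate_overall: float | None = None
    success_rate_active: float | None = None

    def predicted(self, name: str) -> str:
        return self.calls[name].predicted

    def sensitivity(self) -> float:
        """Correct actives / true actives, as a proportion in [0, 1]."""
        if self.n_true_active in (None, 0):
            raise ValidationError("report is unscored or has no true actives")
        return self.n_correct_active / self.n_true_active

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": c.name,
                "predicted": c.predicted,
                "ambiguous": c.ambiguous,
            }
            for c in self.calls.values()
        ]
        return pd.DataFrame(rows)


def _auto_noise_floor(cov: np.ndarray) -> float:
    """Robust covariance noise scale: 3 * 1.4826 * MAD about the median.

    On noise-free data most buckets have exactly zero covariance, the MAD
    collapses to ~0 and the floor degenerates to "any nonzero covariance".
    """
    mad = np.median(np.abs(cov - np.median(cov)))
    return float(3.0 * 1.4826 * mad)


def detect_compounds(
    ps: Pseudospectrum,
    lib: PeakLibrary,
    opts: CorrelationOptions = CorrelationOptions(),
    min_peak_fraction: float = 0.5,
    noise_floor: float | None = None,
    ppm_tolerance: float | None = None,
) -> DetectionReport:
    """Call each library compound from a total-HetCA pseudospectrum.

    Each diagnostic peak is matched to the kept bucket with the largest
    |covariance| within ``ppm_tolerance`` of its reference position
    (default: one bucket width, the slack an analyst allows when matching a
    standard's peak list against a pseudospectrum whose shifts moved
    slightly); peaks with no kept bucket in range — e.g. inside an excluded
    solvent region — contribute nothing.  A compound is *detected* when at
    least ``min_peak_fraction`` of its diagnostic peaks map to buckets
    whose |covariance| exceeds the noise floor.  A detected compound is *predicted active* when at least
    that same fraction of its supporting buckets shows r >=
    ``opts.high_corr_threshold`` with positive covariance ("deep red"
    variables); *predicted inactive* when the median r of its supporting
    buckets falls below ``opts.low_corr_threshold``; anything in between is
    an ambiguous call, reported as inactive with the flag set.
    """
    if not 0 < min_peak_fraction <= 1:
        raise ValidationError("min_peak_fraction must lie in (0, 1]")
    centers = ps.ppm_centers
    if centers.size == 0:
        raise ValidationError("empty pseudospectrum")
    order = np.argsort(centers)
    sorted_centers = centers[order]
    spacing = (
        float(np.median(np.diff(sorted_centers))) if centers.size > 1 else np.inf
    )
    tol = max(spacing / 2, ppm_tolerance if ppm_tolerance is not None else spacing)
    floor = _auto_noise_floor(ps.covariance) if noise_floor is None else noise_floor

    calls: dict[str, CompoundCall] = {}
    for name, peaks in lib.compounds.items():
        rows = []
        for p in peaks:
            i0 = int(np.searchsorted(sorted_centers, p - tol, side="left"))
            i1 = int(np.searchsorted(sorted_centers, p + tol, side="right"))
            if i0 == i1:  # no kept bucket in range (excluded region/off-axis)
                rows.append((p, np.nan, np.nan, np.nan))
                continue
            cand = order[i0:i1]
            jj = int(cand[np.argmax(np.abs(ps.covariance[cand]))])
            rows.append((p, centers[jj], ps.covariance[jj], ps.correlation[jj]))
        ev = pd.DataFrame(
            rows, columns=["peak_ppm", "bucket_ppm", "covariance", "r"]
        )
        supported = ev.dropna(subset=["covariance"])
        supported = supported[supported["covariance"].abs() > floor]
        if len(supported) < min_peak_fraction * len(peaks):
            calls[name] = CompoundCall(name, NOT_DETECTED, evidence=ev)
            continue
        deep_red = (supported["r"] >= opts.high_corr_threshold) & (
            supported["covariance"] > 0
        )
        if deep_red.sum() >= min_peak_fraction * len(supported):
            calls[name] = CompoundCall(name, ACTIVE, evidence=ev)
        elif supported["r"].median() < opts.low_corr_threshold:
            calls[name] = CompoundCall(name, INACTIVE, evidence=ev)
        else:
            calls[name] = CompoundCall(name, INACTIVE, ambiguous=True, evidence=ev)
    return DetectionReport(
        calls=calls,
        high_corr_threshold=opts.high_corr_threshold,
        low_corr_threshold=opts.low_corr_threshold,
        min_peak_fraction=min_peak_fraction,
        noise_floor=floor,
    )


def exact_rate(numerator: int, denominator: int) -> float:
    """Percentage from exact rational arithmetic, one decimal, half-up.

    21/30 -> 70.0, 27/33 -> 81.8, 10/19 -> 52.6, 12/19 -> 63.2.
    """
    if denominator <= 0:
        raise ValidationError("rate denominator must be positive")
    frac = Fraction(100 * numerator, denominator)
    exact = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def score_detection(
    report: DetectionReport, truth_labels: dict[str, bool]
) -> DetectionReport:
    """Fill the aggregate tallies of a detection report against truth.

    * identified = compounds detected (called active or inactive);
    * correct    = identified compounds whose call matches truth;
    * FP         = true-inactive predicted active;
    * FN         = true-active predicted inactive;
    * overall success rate  = 100 * correct / identified;
    * active success rate   = 100 * correctly-called actives / true actives
      (undetected actives stay in the denominator but are not FNs).
    """
    missing = [n for n in report.calls if n not in truth_labels]
    if missing:
        raise ValidationError(
            f"compounds absent from truth labels: {', '.join(missing)}"
        )
    identified = [c for c in report.calls.values() if c.predicted != NOT_DETECTED]
    n_identified = len(identified)
    n_correct = sum(
        1
        for c in identified
        if (c.predicted == ACTIVE) == bool(truth_labels[c.name])
    )
    fp = sum(
        1 for c in identified if c.predicted == ACTIVE and not truth_labels[c.name]
    )
    fn = sum(
        1 for c in identified if c.predicted == INACTIVE and truth_labels[c.name]
    )
    true_actives = [n for n in report.calls if truth_labels[n]]
    correct_active = sum(
        1 for n in true_actives if report.calls[n].predicted == ACTIVE
    )
    report.n_identified = n_identified
    report.n_correct = n_correct
    report.false_positives = fp
    report.false_negatives = fn
    report.n_true_active = len(true_actives)
    report.n_correct_active = correct_active
    report.success_rate_overall = (
        exact_rate(n_correct, n_identified) if n_identified else 0.0
    )
    report.success_rate_active = (
        exact_rate(correct_active, len(true_actives)) if true_actives else 0.0
    )
    return report


def concentration_activity_audit(
    truth: GroundTruth, activity: ActivityTable
) -> pd.Series:
    """Pearson r between each compound's concentration profile and activity.

    The diagnostic "integration table" step: when a call looks wrong, the
    per-compound concentration/activity correlation explains it (a high r
    for an inactive co-eluter, a near-zero r for an overshadowed active).
    Zero-variance columns get r = 0.
    """
    y = activity.values_for(list(truth.fraction_ids))
    if np.ptp(y) == 0.0:
        raise ValidationError("activity has zero variance; audit is undefined")
    out = {}
    yc = y - y.mean()
    sy = y.std(ddof=1)
    for j, name in enumerate(truth.compound_names):
        x = truth.concentration[:, j]
        sx = x.std(ddof=1)
        if sx == 0.0:
            out[name] = 0.0
            continue
        cov = (x - x.mean()) @ yc / (y.size - 1)
        out[name] = float(np.clip(cov / (sx * sy), -1.0, 1.0))
    return pd.Series(out, name="concentration_activity_r")
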