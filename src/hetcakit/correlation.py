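"""Heterocovariance analysis (HetCA), STOCSY and sliding-window partial HetCA.

HetCA correlates a matrix of bucketed fraction spectra (rows = fractions,
columns = spectral variables) with a matched bioactivity vector.  For every
variable j it reports

* the sample cross-covariance  c_j = sum_i (x_ij - xbar_j)(y_i - ybar) / (n - 1)
* the Pearson correlation      r_j = c_j / (s_j * s_y)

with sample (n - 1) standard deviations, mirroring the MATLAB
``crosscov``/``corr`` conventions.  Displayed against the ppm axis this is a
*pseudospectrum*: a plot shaped like a 1H NMR spectrum whose peak heights are
covariances and whose colors are correlation coefficients — positive peaks
mean the variable rises with activity.

STOCSY is the same estimator with a chosen spectral variable (the "driver"
peak) standing in for the activity vector; it picks out the other resonances
of the same molecule through their intensity multicollinearity.  Partial
HetCA repeats HetCA on consecutive sliding windows of fractions to localize
contributions that a single total pseudospectrum averages away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import ActivityTable, BucketTable, ValidationError

__all__ = [
    "Pseudospectrum",
    "CorrelationOptions",
    "hetca",
    "stocsy",
    "partial_hetca",
]


@dataclass(frozen=True)
class CorrelationOptions:
    """Knobs shared by the correlation estimators and downstream calls.

    high_corr_threshold
        |r| above which a variable is rendered "deep red" and counts as
        evidence of activity in detection calls.
    low_corr_threshold
        median r below which a detected compound is called inactive.
    zero_variance_r
        correlation assigned to a variable (or driver) with zero variance;
        0 keeps pseudospectra plottable.
    """

    high_corr_threshold: float = 0.8
    low_corr_threshold: float = 0.5
    zero_variance_r: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.high_corr_threshold <= 1.0:
            raise ValidationError("high_corr_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class Pseudospectrum:
    """Per-variable covariance and correlation against a response vector."""

    ppm_centers: np.ndarray
    covariance: np.ndarray
    correlation: np.ndarray
    n_samples: int
    source: str = "total-hetca"
    fraction_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_centers, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        r = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "ppm_centers", ppm)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "correlation", r)
        if not (ppm.shape == cov.shape == r.shape):
            raise ValidationError("pseudospectrum arrays must share one length")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValidationError("correlation outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ppm": self.ppm_centers,
                "covariance": self.covariance,
                "correlation": self.correlation,
                "source": self.source,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _column_stats(x: np.ndarray, y: np.ndarray, zero_variance_r: float):
    """Vectorized per-column covariance/correlation of x's columns vs y."""
    n = y.size
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    cov = xc.T @ yc / (n - 1)
    sx = x.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sx * sy)
    dead = sx == 0.0
    r[dead] = zero_variance_r
    cov[dead] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return cov, r


def _response_vector(buckets: BucketTable, activity: ActivityTable) -> np.ndarray:
    return activity.values_for(list(buckets.fraction_ids))


def hetca(
    buckets: BucketTable,
    activity: ActivityTable,
    opts: CorrelationOptions = CorrelationOptions(),
) -> Pseudospectrum:
    """Total heterocovariance: correlate every bucket with % inhibition.

    Requires at least three fractions and non-constant activity.  Variables
    with zero variance get ``opts.zero_variance_r`` (default 0) and zero
    covariance, so sign(c) == sign(r) wherever both are nonzero.
    """
    n = len(buckets)
    if n < 3:
        raise ValidationError(f"HetCA needs >= 3 fractions, got {n}")
    y = _response_vector(buckets, activity)
    if np.ptp(y) == 0.0:
        raise ValidationError(
            "activity has zero variance across fractions; HetCA is undefined"
        )
    cov, r = _column_stats(buckets.values, y, opts.zero_variance_r)
    return Pseudospectrum(
        ppm_centers=buckets.centers,
        covariance=cov,
        correlation=r,
        n_samples=n,
        source="total-hetca",
        fraction_ids=buckets.fraction_ids,
    )


def stocsy(
    buckets: BucketTable,
    driver_ppm: float,
    opts: CorrelationOptions = CorrelationOptions(),
) -> Pseudospectrum:
    """Statistical total correlation: every bucket vs the driver-peak bucket.

    ``driver_ppm`` is resolved to the nearest kept bucket (within half a
    bucket width); a driver falling in an excluded region is an error.
    """
    n = len(buckets)
    if n < 3:
        raise ValidationError(f"STOCSY needs >= 3 fractions, got {n}")
    j = buckets.nearest_bucket(driver_ppm)
    if j is None:
        raise ValidationError(
            f"driver peak at {driver_ppm} ppm maps to no kept bucket "
            "(inside an exclusion region or off-axis)"
        )
    y = buckets.values[:, j]
    if np.ptp(y) == 0.0:
        raise ValidationError(
            f"driver bucket at {buckets.centers[j]:.4f} ppm has zero variance"
        )
    cov, r = _column_stats(buckets.values, y, opts.zero_variance_r)
    return Pseudospectrum(
        ppm_centers=buckets.centers,
        covariance=cov,
        correlation=r,
        n_samples=n,
        source=f"stocsy({buckets.centers[j]:.4f} ppm)",
        fraction_ids=buckets.fraction_ids,
    )


def partial_hetca(
    buckets: BucketTable,
    activity: ActivityTable,
    window: int = 5,
    opts: CorrelationOptions = CorrelationOptions(),
    fraction_ids: Sequence[str] | None = None,
) -> list[Pseudospectrum]:
    """HetCA over consecutive sliding windows of ``window`` fractions.

    With n fractions and stride 1 this yields ``n - window + 1``
    pseudospectra, each tagged with its fraction range — e.g. the 51
    fractions Fr20–Fr70 with window 5 give 47 plots.  ``fraction_ids``
    restricts (and orders) the fraction range first.
    """
    if fraction_ids is not None:
        buckets = buckets.select(list(fraction_ids))
    n = len(buckets)
    if window < 3:
        raise ValidationError("window must be >= 3 fractions")
    if window > n:
        raise ValidationError(f"window {window} exceeds the {n} available fractions")
    out: list[Pseudospectrum] = []
    ids = list(buckets.fraction_ids)
    for start in range(n - window + 1):
        sub_ids = ids[start : start + window]
        sub = buckets.select(sub_ids)
        y = _response_vector(sub, activity)
        if np.ptp(y) == 0.0:
            # a window of flat activity carries no correlation information;
            # emit an all-zero pseudospectrum instead of aborting the sweep
            cov = np.zeros(sub.n_buckets)
            r = np.full(sub.n_buckets, opts.zero_variance_r)
        else:
            cov, r = _column_stats(sub.values, y, opts.zero_variance_r)
        out.append(
            Pseudospectrum(
                ppm_centers=sub.centers,
                covariance=cov,
                correlation=r,
                n_samples=window,
                source=f"partial-hetca({sub_ids[0]}..{sub_ids[-1]})",
                fraction_ids=tuple(sub_ids),
            )
        )
    return out
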