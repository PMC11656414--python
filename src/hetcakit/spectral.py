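"""Data model and I/O for fraction spectra, bioactivity and bucketing.

The central container is a :class:`SpectrumSet`: a stack of 1D proton NMR
spectra, one per chromatographic fraction, sharing a common chemical-shift
axis.  Spectra are stored in elution order; the axis follows the NMR display
convention (descending ppm, left to right).  Bioactivity lives in an
:class:`ActivityTable` keyed by fraction id.

Solvent and water resonances are removed with :func:`apply_exclusions`
before any statistics, and :func:`bucket` integrates the remaining points
into fixed-width ppm intervals (buckets) that serve as the statistical
variables for correlation analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PpmAxis",
    "Spectrum",
    "SpectrumSet",
    "ActivityTable",
    "ExclusionRegion",
    "BucketTable",
    "DEFAULT_EXCLUSIONS",
    "read_spectrum_matrix",
    "write_spectrum_matrix",
    "read_activity_table",
    "apply_exclusions",
    "bucket",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class PpmAxis:
    """Chemical-shift axis in ppm, strictly monotone (descending for display)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValidationError("ppm axis needs at least two points")
        if not np.all(np.isfinite(values)):
            raise ValidationError("ppm axis contains non-finite values")
        d = np.diff(values)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def descending(self) -> bool:
        return self.values[0] > self.values[-1]

    @property
    def resolution(self) -> float:
        """Median ppm spacing between adjacent points (positive)."""
        return float(np.median(np.abs(np.diff(self.values))))

    @property
    def lo(self) -> float:
        return float(self.values.min())

    @property
    def hi(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class Spectrum:
    """One fraction's 1D spectrum: a label plus intensities on a shared axis."""

    fraction_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.ndim != 1:
            raise ValidationError("intensities must be a 1D vector")
        if not np.all(np.isfinite(y)):
            raise ValidationError(
                f"spectrum {self.fraction_id!r} contains non-finite intensities"
            )


@dataclass(frozen=True)
class SpectrumSet:
    """Fraction x ppm intensity matrix; row order is elution order."""

    axis: PpmAxis
    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        n_axis = len(self.axis)
        ids = [s.fraction_id for s in spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate fraction ids: {', '.join(dupes)}")
        for s in spectra:
            if s.intensities.size != n_axis:
                raise ValidationError(
                    f"spectrum {s.fraction_id!r} has {s.intensities.size} points, "
                    f"axis has {n_axis}"
                )

    @property
    def fraction_ids(self) -> list[str]:
        return [s.fraction_id for s in self.spectra]

    @property
    def matrix(self) -> np.ndarray:
        """n_fractions x n_points intensity matrix (rows in elution order)."""
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def select(self, fraction_ids: Sequence[str]) -> "SpectrumSet":
        """Subset (and reorder) fractions by id."""
        by_id = {s.fraction_id: s for s in self.spectra}
        missing = [f for f in fraction_ids if f not in by_id]
        if missing:
            raise ValidationError(f"unknown fraction ids: {', '.join(missing)}")
        return SpectrumSet(self.axis, tuple(by_id[f] for f in fraction_ids))

    @classmethod
    def from_matrix(
        cls, ppm: np.ndarray, matrix: np.ndarray, fraction_ids: Sequence[str]
    ) -> "SpectrumSet":
        matrix = np.asarray(matrix, dtype=float)
        axis = PpmAxis(np.asarray(ppm, dtype=float))
        if not axis.descending:
            # store in NMR display order; reverse columns consistently
            axis = PpmAxis(axis.values[::-1])
            matrix = matrix[:, ::-1]
        spectra = tuple(
            Spectrum(str(f), row) for f, row in zip(fraction_ids, matrix, strict=True)
        )
        return cls(axis, spectra)


@dataclass(frozen=True)
class ActivityTable:
    """Per-fraction % DPPH inhibition: mean over replicates, SD, and N."""

    fraction_ids: tuple[str, ...]
    mean_inhibition: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(f) for f in self.fraction_ids)
        mean = np.asarray(self.mean_inhibition, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        n = np.asarray(self.n_replicates, dtype=int)
        object.__setattr__(self, "fraction_ids", ids)
        object.__setattr__(self, "mean_inhibition", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "n_replicates", n)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate fraction ids in activity table")
        if not (mean.shape == sd.shape == (len(ids),) and n.shape == (len(ids),)):
            raise ValidationError("activity table columns have mismatched lengths")
        if np.any(mean < 0) or np.any(mean > 100):
            raise ValidationError("mean inhibition must lie in [0, 100] %")
        if np.any(sd < 0):
            raise ValidationError("inhibition SD must be >= 0")

    def values_for(self, fraction_ids: Sequence[str]) -> np.ndarray:
        """Mean inhibition aligned to the given fraction order."""
        lookup = dict(zip(self.fraction_ids, self.mean_inhibition))
        missing = [f for f in fraction_ids if f not in lookup]
        if missing:
            raise ValidationError(
                f"fractions missing from activity table: {', '.join(missing)}"
            )
        return np.array([lookup[f] for f in fraction_ids], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_id": list(self.fraction_ids),
                "mean_inhibition": self.mean_inhibition,
                "sd": self.sd,
                "n": self.n_replicates,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ExclusionRegion:
    """A ppm interval removed from integration (e.g. residual solvent)."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"exclusion region needs lo < hi, got {self.lo}..{self.hi}")

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        return (ppm >= self.lo) & (ppm <= self.hi)

    def overlaps(self, lo: float, hi: float) -> bool:
        return (self.lo < hi) and (lo < self.hi)


#: Residual methanol-d4 signal and the water peak, the two regions routinely
#: excluded from integration of methanol-d4 fraction spectra.
DEFAULT_EXCLUSIONS: tuple[ExclusionRegion, ...] = (
    ExclusionRegion(3.29, 3.36, "methanol-d4"),
    ExclusionRegion(4.76, 4.82, "water"),
)


def _normalize_regions(regions: Iterable[ExclusionRegion]) -> list[ExclusionRegion]:
    """Sort and merge overlapping regions into a disjoint list."""
    regs = sorted(regions, key=lambda r: r.lo)
    merged: list[ExclusionRegion] = []
    for r in regs:
        if merged and r.lo <= merged[-1].hi:
            last = merged.pop()
            merged.append(
                ExclusionRegion(last.lo, max(last.hi, r.hi), last.label or r.label)
            )
        else:
            merged.append(r)
    return merged


def apply_exclusions(
    s: SpectrumSet, regions: Sequence[ExclusionRegion] = DEFAULT_EXCLUSIONS
) -> SpectrumSet:
    """Drop every axis point falling inside any exclusion region.

    The relative order of surviving points is preserved; the operation is
    idempotent.  Raises if a region lies outside the axis range or if nothing
    would survive.
    """
    regions = list(regions)
    if not regions:
        return s
    ppm = s.axis.values
    for r in regions:
        if r.hi < s.axis.lo or r.lo > s.axis.hi:
            raise ValidationError(
                f"exclusion region {r.lo}..{r.hi} ppm lies outside the axis "
                f"range {s.axis.lo}..{s.axis.hi}"
            )
    keep = np.ones(ppm.size, dtype=bool)
    for r in _normalize_regions(regions):
        keep &= ~r.contains(ppm)
    if keep.sum() < 2:
        raise ValidationError("exclusion regions would remove the entire axis")
    axis = PpmAxis(ppm[keep])
    spectra = tuple(
        Spectrum(sp.fraction_id, sp.intensities[keep]) for sp in s.spectra
    )
    return SpectrumSet(axis, spectra)


@dataclass(frozen=True)
class BucketTable:
    """Integrated spectral variables: fractions x kept buckets.

    ``edges`` holds the half-open ascending-ppm interval ``[lo, hi)`` of each
    *kept* bucket; ``values[i, j]`` is the point-sum of fraction ``i`` inside
    bucket ``j``.  Buckets overlapping an exclusion region were dropped before
    construction and are recorded in ``excluded_edges`` for provenance.
    """

    fraction_ids: tuple[str, ...]
    edges: np.ndarray  # (n_buckets, 2) ascending ppm
    values: np.ndarray  # (n_fractions, n_buckets)
    excluded_edges: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=float)
    )

    def __post_init__(self) -> None:
        ids = tuple(str(f) for f in self.fraction_ids)
        edges = np.asarray(self.edges, dtype=float).reshape(-1, 2)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "fraction_ids", ids)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", values)
        if edges.shape[0] == 0:
            raise ValidationError("no buckets survive exclusion")
        if values.shape != (len(ids), edges.shape[0]):
            raise ValidationError("bucket value matrix shape mismatch")

    @property
    def centers(self) -> np.ndarray:
        """ppm center of each kept bucket."""
        return self.edges.mean(axis=1)

    @property
    def n_buckets(self) -> int:
        return int(self.edges.shape[0])

    def __len__(self) -> int:
        return len(self.fraction_ids)

    def select(self, fraction_ids: Sequence[str]) -> "BucketTable":
        idx = {f: i for i, f in enumerate(self.fraction_ids)}
        missing = [f for f in fraction_ids if f not in idx]
        if missing:
            raise ValidationError(f"unknown fraction ids: {', '.join(missing)}")
        rows = [idx[f] for f in fraction_ids]
        return replace(
            self, fraction_ids=tuple(fraction_ids), values=self.values[rows]
        )

    def nearest_bucket(self, ppm: float) -> int | None:
        """Index of the kept bucket whose interval contains ``ppm``.

        Falls back to the nearest bucket center within half a bucket width;
        returns ``None`` when the position maps to no kept bucket (e.g. it
        sits inside an excluded region).
        """
        lo, hi = self.edges[:, 0], self.edges[:, 1]
        inside = np.flatnonzero((ppm >= lo) & (ppm < hi))
        if inside.size:
            return int(inside[0])
        centers = self.centers
        j = int(np.argmin(np.abs(centers - ppm)))
        half_width = (hi[j] - lo[j]) / 2.0
        if abs(centers[j] - ppm) <= half_width:
            return j
        return None


def bucket(
    s: SpectrumSet,
    width: float,
    regions: Sequence[ExclusionRegion] = DEFAULT_EXCLUSIONS,
) -> BucketTable:
    """Integrate spectra into uniform ``width``-ppm buckets.

    Buckets are half-open ``[lo, hi)`` intervals laid out in ascending ppm
    from the axis minimum; the final bucket absorbs the axis-end remainder so
    that every point belongs to exactly one bucket.  A bucket value is the
    plain sum of the point intensities inside the interval, so the total over
    all kept buckets equals the point-sum over non-excluded regions exactly.
    Buckets that overlap an exclusion region, even partially, are dropped.
    """
    if width <= 0:
        raise ValidationError("bucket width must be positive")
    res = s.axis.resolution
    if width < res - 1e-12:
        raise ValidationError(
            f"bucket width {width} ppm is below the axis resolution {res:.6g} ppm"
        )
    ppm = s.axis.values
    lo, hi = s.axis.lo, s.axis.hi
    # uniform-width tiling from the axis minimum; the final bucket is the
    # axis-end remainder (shorter, or stretched to catch the last point)
    n_buckets = max(1, int(np.ceil((hi - lo) / width - 1e-9)))
    starts = lo + width * np.arange(n_buckets)
    ends = starts + width
    ends[-1] = max(ends[-1], hi + 0.5 * res)

    regions = _normalize_regions(regions) if regions else []
    keep_mask = np.array(
        [not any(r.overlaps(a, b) for r in regions) for a, b in zip(starts, ends)]
    )
    if not keep_mask.any():
        raise ValidationError("no buckets survive exclusion")

    # assign each point to its bucket, then sum per (fraction, bucket);
    # clipping routes axis-end remainder points into the last bucket
    idx = np.clip(
        np.floor((ppm - lo) / width + 1e-9).astype(int), 0, n_buckets - 1
    )
    mat = s.matrix
    sums = np.zeros((mat.shape[0], n_buckets))
    np.add.at(sums.T, idx, mat.T)

    kept = np.flatnonzero(keep_mask)
    dropped = np.flatnonzero(~keep_mask)
    edges = np.column_stack([starts[kept], ends[kept]])
    excluded = np.column_stack([starts[dropped], ends[dropped]])
    return BucketTable(
        fraction_ids=tuple(s.fraction_ids),
        edges=edges,
        values=sums[:, kept],
        excluded_edges=excluded,
    )


# ---------------------------------------------------------------------------
# Delimited-matrix I/O
#
# Interchange layout: row 1 = "ppm" followed by the axis values; each further
# row = fraction id followed by that fraction's intensities.

def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_spectrum_matrix(path, sep: str | None = None) -> SpectrumSet:
    """Read a delimited fraction x ppm intensity matrix.

    Raises on ragged rows, duplicated fraction ids and non-numeric cells
    (reported with row/column position).
    """
    if sep is None:
        sep = _sniff_sep(path)
    with open(path) as fh:
        rows = [line.rstrip("\n").split(sep) for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValidationError("spectrum matrix needs a ppm header and >= 1 fraction row")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValidationError(
                f"ragged row {i}: {len(row)} fields, header has {width}"
            )

    def parse(cell: str, row: int, col: int) -> float:
        try:
            return float(cell)
        except ValueError:
            raise ValidationError(
                f"non-numeric value {cell!r} at row {row}, column {col}"
            ) from None

    ppm = np.array([parse(c, 1, j + 2) for j, c in enumerate(header[1:])])
    ids = [row[0] for row in rows[1:]]
    matrix = np.array(
        [
            [parse(c, i + 2, j + 2) for j, c in enumerate(row[1:])]
            for i, row in enumerate(rows[1:])
        ]
    )
    return SpectrumSet.from_matrix(ppm, matrix, ids)


def write_spectrum_matrix(s: SpectrumSet, path, sep: str = "\t") -> None:
    """Write the delimited matrix accepted by :func:`read_spectrum_matrix`."""
    buf = io.StringIO()
    buf.write("ppm" + sep + sep.join(repr(float(v)) for v in s.axis.values) + "\n")
    for sp in s.spectra:
        buf.write(
            sp.fraction_id
            + sep
            + sep.join(repr(float(v)) for v in sp.intensities)
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_activity_table(path) -> ActivityTable:
    """Read a CSV with columns fraction_id, mean_inhibition, sd, n."""
    df = pd.read_csv(path, dtype={"fraction_id": str})
    required = {"fraction_id", "mean_inhibition"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"activity table must provide columns {sorted(required)}"
        )
    sd = df["sd"] if "sd" in df.columns else pd.Series(0.0, index=df.index)
    n = df["n"] if "n" in df.columns else pd.Series(1, index=df.index)
    return ActivityTable(
        fraction_ids=tuple(df["fraction_id"].astype(str)),
        mean_inhibition=df["mean_inhibition"].to_numpy(float),
        sd=sd.to_numpy(float),
        n_replicates=n.to_numpy(int),
    )
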