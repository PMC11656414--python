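"""Ground-truthed simulation of fractionated mixtures.

This module generates the kind of data a bioassay-guided fractionation
campaign produces — a series of chromatographic fractions, each with a 1D
proton NMR spectrum and a % DPPH-inhibition value — from a fully known
composition, so that correlation-based detection can be scored against
truth.  It emulates:

* **FCPC-like elution**: each compound's amount spreads over consecutive
  fractions as a discretized Gaussian (center, width in fraction units),
  renormalized so mass balance is exact.  Overlapping profiles are the norm,
  as in real counter-current separations after pooling.
* **Additive, saturating antiradical activity**: the radical-scavenging load
  of fraction i is p_i = sum_k conc_ik / EC_k, where EC_k is the
  concentration at which compound k alone reaches half-saturation.  Mean
  inhibition is 100 * p_i / (1 + p_i): additive at low load, and a plateau
  near 100 % at high load where the concentration–activity relationship
  (and hence correlation) breaks down.
* **Spectra**: Lorentzian multiplets (explicit peak lists), per-fraction,
  per-compound chemical-shift jitter (all peaks of a compound move
  together, as for ionizable compounds whose shifts track concentration),
  and additive Gaussian noise.
* **Solubility dropout**: an optional per-compound concentration cap applied
  to the *spectra only* — the bioassay sees the true concentration — which
  reproduces the inconsistency between NMR data and biological response
  seen when a compound saturates its NMR sample.

A compound is labelled *active* when its solo inhibition at the reference
concentration exceeds 50 %, i.e. when EC < reference_concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .spectral import ActivityTable, PpmAxis, Spectrum, SpectrumSet, ValidationError

__all__ = [
    "CompoundSpec",
    "MixtureDesign",
    "GroundTruth",
    "simulate_elution",
    "simulate_activity",
    "simulate_spectra",
    "simulate",
    "preset",
    "PRESET_NAMES",
]

#: Lorentzian tails are evaluated out to this many FWHMs on either side of
#: each (jittered) peak center; beyond that the residual area is < 0.2 %.
_PEAK_WINDOW_FWHM = 200.0


@dataclass(frozen=True)
class CompoundSpec:
    """One mixture constituent: NMR multiplet list, potency and elution."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]  # (center ppm, fwhm ppm, area)
    potency_ec: float  # concentration at half-saturation; inf = inactive
    elution_center: float  # fraction index (1-based, may be fractional)
    elution_width: float  # Gaussian sd in fraction units
    amount: float  # total arbitrary mass distributed over fractions
    nmr_solubility_cap: float | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValidationError(f"{self.name}: needs at least one peak")
        for c, w, a in self.peaks:
            if w <= 0 or a <= 0:
                raise ValidationError(
                    f"{self.name}: peak widths and areas must be positive"
                )
        if not self.potency_ec > 0:
            raise ValidationError(f"{self.name}: EC must be positive (inf = inactive)")
        if self.elution_width <= 0:
            raise ValidationError(f"{self.name}: elution width must be positive")
        if self.amount < 0:
            raise ValidationError(f"{self.name}: amount must be >= 0")


def default_axis(lo: float = 0.2, hi: float = 10.0, step: float = 0.001) -> PpmAxis:
    """Descending ppm axis covering the usual 1H window at ~0.001 ppm/pt."""
    n = int(round((hi - lo) / step)) + 1
    return PpmAxis(np.linspace(hi, lo, n))


@dataclass(frozen=True)
class MixtureDesign:
    """Everything needed to generate one simulated fractionation study."""

    compounds: tuple[CompoundSpec, ...]
    n_fractions: int
    axis: PpmAxis = field(default_factory=default_axis)
    noise_sd: float = 0.0
    jitter_sd: float = 0.0  # ppm, per fraction per compound
    activity_replicates: int = 3
    activity_noise_sd: float = 0.0  # % inhibition per replicate
    reference_concentration: float = 1.0  # defines the 50 % activity rule
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValidationError("need at least two fractions")
        if self.reference_concentration <= 0:
            raise ValidationError("reference concentration must be positive")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValidationError("compound names must be unique")

    @property
    def fraction_ids(self) -> list[str]:
        return [f"Fr{k:02d}" for k in range(1, self.n_fractions + 1)]

    @property
    def compound_names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def _rng(self, stream: int) -> np.random.Generator:
        # one independent, order-insensitive stream per purpose
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class GroundTruth:
    """True composition and activity bookkeeping for a simulated design."""

    fraction_ids: tuple[str, ...]
    compound_names: tuple[str, ...]
    concentration: np.ndarray  # n_fractions x n_compounds
    active_labels: dict[str, bool]
    component_inhibition: np.ndarray | None = None  # same shape, % units

    def concentration_of(self, name: str) -> np.ndarray:
        j = self.compound_names.index(name)
        return self.concentration[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.concentration,
            index=list(self.fraction_ids),
            columns=list(self.compound_names),
        )
        df.index.name = "fraction_id"
        return df


def simulate_elution(design: MixtureDesign) -> GroundTruth:
    """Distribute each compound's amount over fractions (Gaussian profile).

    Deterministic given the design.  Weights are renormalized so each
    concentration column sums to the compound's amount exactly; a compound
    whose continuous profile would lose more than 1 % of its mass outside
    the fraction range is rejected.
    """
    n = design.n_fractions
    idx = np.arange(1, n + 1, dtype=float)
    cols = []
    for comp in design.compounds:
        c, w = comp.elution_center, comp.elution_width
        coverage = norm.cdf((n + 0.5 - c) / w) - norm.cdf((0.5 - c) / w)
        if coverage < 0.99:
            raise ValidationError(
                f"{comp.name}: elution profile (center {c}, width {w}) loses "
                f"{100 * (1 - coverage):.1f}% of its mass outside the "
                f"{n} collected fractions"
            )
        z = (idx - c) / w
        with np.errstate(under="ignore"):
            weights = np.exp(-0.5 * z * z)
        if weights.max() > 0.0:
            # drop numerically negligible tails so a near-delta profile is one
            weights[weights < weights.max() * 1e-15] = 0.0
        total = weights.sum()
        if total <= 0.0:  # delta limit: width far below fraction spacing
            weights = np.zeros(n)
            weights[int(np.clip(round(c), 1, n)) - 1] = 1.0
            total = 1.0
        cols.append(comp.amount * weights / total)
    conc = np.column_stack(cols) if cols else np.zeros((n, 0))
    labels = {
        comp.name: comp.potency_ec < design.reference_concentration
        for comp in design.compounds
    }
    return GroundTruth(
        fraction_ids=tuple(design.fraction_ids),
        compound_names=tuple(design.compound_names),
        concentration=conc,
        active_labels=labels,
    )


def _inhibition_from_load(load: np.ndarray) -> np.ndarray:
    return 100.0 * load / (1.0 + load)


def simulate_activity(truth: GroundTruth, design: MixtureDesign) -> ActivityTable:
    """Saturating-additive DPPH response with replicate noise.

    The per-fraction load p_i = sum_k conc_ik / EC_k maps to a mean
    inhibition 100 p/(1+p); replicate measurements add truncated Gaussian
    noise (sd = ``activity_noise_sd``) and are summarized as mean ± SD.
    Also stores each compound's true inhibition share on the ground truth.
    """
    ec = np.array([c.potency_ec for c in design.compounds])
    loads = truth.concentration / ec  # n_fractions x n_compounds
    p = loads.sum(axis=1)
    mean_true = _inhibition_from_load(p)
    # exact attribution: component k's share of the saturated response
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(p[:, None] > 0, loads / (1.0 + p[:, None]) * 100.0, 0.0)
    object.__setattr__(truth, "component_inhibition", share)

    reps = design.activity_replicates
    if design.activity_noise_sd > 0:
        rng = design._rng(2)
        noise = rng.normal(0.0, design.activity_noise_sd, size=(reps, p.size))
        obs = np.clip(mean_true[None, :] + noise, 0.0, 100.0)
        mean = obs.mean(axis=0)
        sd = obs.std(axis=0, ddof=1) if reps > 1 else np.zeros_like(mean)
    else:
        mean = mean_true
        sd = np.zeros_like(mean)
    return ActivityTable(
        fraction_ids=tuple(design.fraction_ids),
        mean_inhibition=mean,
        sd=sd,
        n_replicates=np.full(p.size, reps),
    )


def _lorentzian_add(
    out: np.ndarray, ppm: np.ndarray, center: float, fwhm: float, area: float
) -> None:
    """Accumulate one Lorentzian line onto ``out`` (windowed evaluation)."""
    gamma = fwhm / 2.0
    half = _PEAK_WINDOW_FWHM * fwhm
    lo_v, hi_v = center - half, center + half
    # ppm is descending -> indices where value in [lo_v, hi_v]
    i0 = np.searchsorted(-ppm, -hi_v, side="left")
    i1 = np.searchsorted(-ppm, -lo_v, side="right")
    seg = ppm[i0:i1]
    if seg.size == 0:
        return
    out[i0:i1] += (area / math.pi) * gamma / ((seg - center) ** 2 + gamma**2)


def simulate_spectra(truth: GroundTruth, design: MixtureDesign) -> SpectrumSet:
    """Synthesize fraction spectra from the concentration matrix.

    Spectrum_i = sum_k min(conc_ik, cap_k) * multiplet_k(jitter_ik) + noise.
    The solubility cap truncates concentrations for spectral synthesis only,
    so bioactivity (computed from the untruncated matrix) can disagree with
    what the NMR sees.  Jitter is one draw per (fraction, compound); all
    peaks of a compound move together.  Reproducible from the design seed.
    """
    ppm = design.axis.values
    lo, hi = design.axis.lo, design.axis.hi
    for comp in design.compounds:
        for c, w, a in comp.peaks:
            if not (lo <= c <= hi):
                raise ValidationError(
                    f"{comp.name}: peak at {c} ppm outside axis {lo}..{hi}"
                )
    n, m = design.n_fractions, len(design.compounds)
    conc = truth.concentration.copy()
    for j, comp in enumerate(design.compounds):
        if comp.nmr_solubility_cap is not None:
            np.minimum(conc[:, j], comp.nmr_solubility_cap, out=conc[:, j])

    if design.jitter_sd > 0:
        jitter = design._rng(0).normal(0.0, design.jitter_sd, size=(n, m))
    else:
        jitter = np.zeros((n, m))

    mat = np.zeros((n, ppm.size))
    if design.jitter_sd == 0:
        # shared compound signatures: one synthesis, one matrix product
        signatures = np.zeros((m, ppm.size))
        for j, comp in enumerate(design.compounds):
            for c, w, a in comp.peaks:
                _lorentzian_add(signatures[j], ppm, c, w, a)
        mat = conc @ signatures
    else:
        tiny = 1e-12
        for i in range(n):
            row = mat[i]
            for j, comp in enumerate(design.compounds):
                cij = conc[i, j]
                if cij <= tiny * max(comp.amount, 1.0):
                    continue
                d = jitter[i, j]
                buf = np.zeros_like(row)
                for c, w, a in comp.peaks:
                    _lorentzian_add(buf, ppm, c + d, w, a)
                row += cij * buf

    if design.noise_sd > 0:
        mat += design._rng(1).normal(0.0, design.noise_sd, size=mat.shape)

    spectra = tuple(
        Spectrum(fid, mat[i]) for i, fid in enumerate(design.fraction_ids)
    )
    return SpectrumSet(design.axis, spectra)


def simulate(design: MixtureDesign) -> tuple[SpectrumSet, ActivityTable, GroundTruth]:
    """Run the full generator: elution -> activity -> spectra."""
    truth = simulate_elution(design)
    activity = simulate_activity(truth, design)
    spectra = simulate_spectra(truth, design)
    return spectra, activity, truth


# ---------------------------------------------------------------------------
# Presets
#
# Named, fully specified designs covering the evaluation scenarios: a simple
# 10-compound / 12-fraction series (artfrct), a 59-compound / 69-fraction
# artificial extract (artextr), and three focused failure-mode designs.

PRESET_NAMES = ("artfrct", "artextr", "coelution-fp", "overshadow-fn", "misalignment")

# candidate peak positions: a 0.05-ppm grid avoiding the solvent exclusion
# windows (with margin), shuffled deterministically per preset
_SOLVENT_AVOID = ((3.25, 3.40), (4.72, 4.86))


def _peak_positions(rng: np.random.Generator, n_needed: int) -> np.ndarray:
    grid = np.arange(0.30, 9.70, 0.05)
    ok = np.ones(grid.size, dtype=bool)
    for lo, hi in _SOLVENT_AVOID:
        ok &= ~((grid >= lo) & (grid <= hi))
    grid = grid[ok]
    if n_needed > grid.size:
        raise ValidationError(
            f"cannot place {n_needed} resolved peaks on the candidate grid"
        )
    chosen = rng.permutation(grid)[:n_needed]
    return chosen + rng.uniform(-0.01, 0.01, size=n_needed)


def _make_compounds(
    rng: np.random.Generator,
    names: Sequence[str],
    ecs: Sequence[float],
    centers: Sequence[float],
    widths: Sequence[float],
    amounts: Sequence[float],
    peaks_per_compound: int = 3,
    fwhm: float = 0.003,
) -> tuple[CompoundSpec, ...]:
    pos = _peak_positions(rng, len(names) * peaks_per_compound)
    comps = []
    for k, name in enumerate(names):
        mypos = pos[k * peaks_per_compound : (k + 1) * peaks_per_compound]
        areas = rng.uniform(1.0, 3.0, size=peaks_per_compound)
        peaks = tuple(
            (float(p), fwhm, float(a)) for p, a in zip(np.sort(mypos)[::-1], areas)
        )
        comps.append(
            CompoundSpec(
                name=name,
                peaks=peaks,
                potency_ec=float(ecs[k]),
                elution_center=float(centers[k]),
                elution_width=float(widths[k]),
                amount=float(amounts[k]),
            )
        )
    return tuple(comps)


def _artextr_design(
    seed: int, noise: bool, jitter: bool, confounders: bool, jitter_sd: float = 0.005
) -> MixtureDesign:
    """59 compounds, 69 pooled fractions, 20 active / 39 inactive.

    With ``confounders=True`` elution centers are drawn across the whole
    run, so actives and inactives co-elute freely (the realistic regime).
    With ``confounders=False`` the 20 actives elute as a broad overlapping
    band in the middle of the run and every inactive elutes well clear of
    it, so no inactive profile tracks the activity — the controlled regime
    in which correlation-based detection should recover every active.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(100,)))
    n_active, n_inactive, n_frac = 20, 39, 69
    names = [f"A{k + 1:02d}" for k in range(n_active)] + [
        f"N{k + 1:02d}" for k in range(n_inactive)
    ]
    ecs = np.concatenate(
        [rng.uniform(0.45, 0.95, n_active), np.full(n_inactive, np.inf)]
    )
    # a few inactives get weak finite potency (still far above the 50 % rule)
    weak = rng.choice(n_inactive, size=8, replace=False)
    ecs[n_active + weak] = rng.uniform(30.0, 300.0, size=8)

    if confounders:
        centers = rng.uniform(9.0, 61.0, n_active + n_inactive)
        widths = rng.uniform(1.5, 3.0, n_active + n_inactive)
    else:
        centers = np.concatenate(
            [
                np.linspace(34.0, 42.0, n_active),
                rng.uniform(8.0, 18.0, 20),
                rng.uniform(54.0, 62.0, n_inactive - 20),
            ]
        )
        widths = np.concatenate(
            [np.full(n_active, 8.0), rng.uniform(1.5, 2.5, n_inactive)]
        )
    amounts = rng.uniform(0.8, 1.5, n_active + n_inactive)
    comps = _make_compounds(rng, names, ecs, centers, widths, amounts)
    return MixtureDesign(
        compounds=comps,
        n_fractions=n_frac,
        noise_sd=0.05 if noise else 0.0,
        jitter_sd=jitter_sd if jitter else 0.0,
        activity_noise_sd=1.0 if noise else 0.0,
        seed=seed,
        name="artextr",
    )


def _artfrct_design(seed: int, noise: bool, jitter: bool) -> MixtureDesign:
    """10 standard compounds combined into 12 simple artificial fractions.

    Concentrations vary sequentially: the five radical scavengers ramp up
    together toward the late fractions while the five inactive compounds
    concentrate early, so the inhibition series has real variance that
    tracks the actives.  One active carries a solubility cap: its NMR
    profile saturates while the bioassay sees the full amount — the
    classic NMR/bioassay inconsistency.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    names = [f"S{k + 1:02d}" for k in range(10)]
    ecs = np.array([0.45, 0.6, 0.8, 0.5, 0.7] + [np.inf] * 5)
    centers = np.array([8.6, 9.0, 9.4, 9.8, 8.2, 2.8, 3.3, 3.8, 4.3, 4.8])
    widths = np.concatenate([np.full(5, 1.0), np.full(5, 0.9)])
    amounts = rng.uniform(0.9, 1.3, 10)
    comps = list(_make_compounds(rng, names, ecs, centers, widths, amounts))
    # S04: strong scavenger with limited NMR solubility (saturated samples)
    comps[3] = replace(comps[3], nmr_solubility_cap=0.05 * comps[3].amount)
    return MixtureDesign(
        compounds=tuple(comps),
        n_fractions=12,
        noise_sd=0.05 if noise else 0.0,
        jitter_sd=0.005 if jitter else 0.0,
        activity_noise_sd=1.0 if noise else 0.0,
        seed=seed,
        name="artfrct",
    )


def _coelution_design(seed: int) -> MixtureDesign:
    """An inactive compound perfectly co-eluting with a strong active.

    Their concentration columns are proportional (r = 1), so every spectral
    variable of the inactive co-eluter correlates with activity exactly as
    the active's do — the false-positive mechanism.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(102,)))
    names = ["active-driver", "coeluter-inactive", "inactive-early", "inactive-late"]
    ecs = [0.15, np.inf, np.inf, np.inf]
    centers = [8.0, 8.0, 4.5, 15.0]
    widths = [2.0, 2.0, 1.2, 1.8]
    amounts = [1.2, 1.0, 1.0, 1.0]
    comps = _make_compounds(rng, names, ecs, centers, widths, amounts)
    return MixtureDesign(
        compounds=comps,
        n_fractions=20,
        noise_sd=0.02,
        jitter_sd=0.0,
        activity_noise_sd=0.5,
        seed=seed,
        name="coelution-fp",
    )


def _overshadow_design(seed: int) -> MixtureDesign:
    """A low-concentration active overshadowed by a stronger neighbor.

    The weak active co-occurs with a much more concentrated active whose
    profile dominates the response; the weak compound's own concentration
    profile no longer tracks activity, so it is called inactive — the
    false-negative mechanism.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(103,)))
    names = ["strong-active", "weak-active", "inactive-early", "inactive-late"]
    ecs = [0.10, 0.30, np.inf, np.inf]
    centers = [13.0, 9.0, 4.5, 16.5]
    widths = [2.0, 2.0, 1.2, 1.3]
    amounts = [1.5, 0.08, 1.0, 1.0]
    comps = _make_compounds(rng, names, ecs, centers, widths, amounts)
    return MixtureDesign(
        compounds=comps,
        n_fractions=20,
        noise_sd=0.02,
        jitter_sd=0.0,
        activity_noise_sd=0.5,
        seed=seed,
        name="overshadow-fn",
    )


def preset(
    name: str,
    seed: int = 0,
    noise: bool = True,
    jitter: bool = True,
    confounders: bool = True,
) -> MixtureDesign:
    """Return a named, fully specified study design.

    ``noise``/``jitter`` toggle spectral noise, replicate noise and
    chemical-shift jitter; ``confounders`` (artextr/misalignment only)
    toggles free co-elution of actives and inactives.  Unknown names raise
    with the list of available presets.
    """
    if name == "artfrct":
        return _artfrct_design(seed, noise, jitter)
    if name == "artextr":
        return _artextr_design(seed, noise, jitter, confounders)
    if name == "coelution-fp":
        return _coelution_design(seed)
    if name == "overshadow-fn":
        return _overshadow_design(seed)
    if name == "misalignment":
        d = _artextr_design(seed, noise=True, jitter=True, confounders=False,
                            jitter_sd=0.01)
        return replace(d, name="misalignment")
    raise ValidationError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
    )
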