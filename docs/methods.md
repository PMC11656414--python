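# Methods

This note documents the statistical models, the synthetic-data generator,
the numeric conventions, and the design decisions behind `hetcakit`, in the
spirit of a package manual's "models" chapter.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The estimators

### Total HetCA

Input: a bucket table `X` (n fractions × p spectral variables, rows in
elution order) and an activity vector `y` (% inhibition per fraction, the
replicate mean).  For each variable j:

- cross-covariance `c_j = Σ_i (x_ij − x̄_j)(y_i − ȳ) / (n − 1)`
- Pearson correlation `r_j = c_j / (s_j s_y)`, with sample (n−1) standard
  deviations.

Sample denominators follow the convention of the MATLAB-style
`crosscov`/`corr` pair commonly used for this analysis; they are fixed, not
configurable, so covariance and correlation always share one convention.
Requirements: at least 3 fractions and non-constant activity (a flat
response carries no information and is rejected rather than silently
returning zeros).  A zero-variance variable gets `r = 0` (configurable via
`CorrelationOptions.zero_variance_r`) and `c = 0`, which keeps
pseudospectra plottable and preserves `sign(c) = sign(r)` wherever both are
nonzero.  Replicate SDs are carried for display; no weighted correlation is
attempted.

No significance testing or multiplicity correction is applied to the p
per-variable correlations: the pseudospectrum is an exploratory, visual
screen whose calls are confirmed compound-wise (STOCSY, standards
comparison), not a hypothesis-testing procedure.  Treating the r values as
tested hypotheses would require an entirely different error model
(autocorrelated variables within a multiplet are not independent tests).

### STOCSY

The same estimator with the activity vector replaced by one chosen spectral
variable (the *driver* peak, resolved to the nearest kept bucket within
half a bucket width).  Because the estimator is shared, `stocsy` with a
driver column equals `hetca` run with that column as the response — a
property the tests assert exactly.

### Partial HetCA

HetCA applied to every consecutive window of `w` fractions (stride 1),
giving `n − w + 1` pseudospectra, each tagged with its fraction range.
Windows whose activity is constant (common in noise-free simulations where
no active elutes) yield an all-zero pseudospectrum instead of aborting the
sweep.  Window results are reported separately and never merged into
total-HetCA detection scores: local correlations are informative for
localization but unstable as global calls (the same compound can appear
decisive in one window and irrelevant in the next).

## 2. Spectral pretreatment

### Exclusion regions

Default masks: residual methanol-d₄ (3.29–3.36 ppm) and water
(4.76–4.82 ppm).  Masking removes axis points before any statistics;
the operation is idempotent and regions are merged if they overlap.

### Bucketing

Uniform half-open intervals `[lo, hi)` laid ascending from the axis
minimum; the final bucket is the axis-end remainder.  A bucket value is
the plain sum of point intensities inside it, so kept-bucket totals equal
the masked point sum exactly (asserted property).  Buckets that overlap an
exclusion region even partially are dropped whole — conservative, and
avoids fractional-bucket bookkeeping.  The `bucket()` default width is
0.001 ppm (essentially per-point statistics); pipeline runs default to
0.01 ppm, coarse enough to absorb the ±1-point residual left by integer
alignment, fine enough to separate resonances 0.03 ppm apart.  Both are
explicit parameters everywhere.  No normalization is applied by default:
the intended inputs are fixed-mass fraction samples (e.g. 3 mg/mL), where
raw integrals are comparable across fractions; total-area or quotient
normalization would re-weight exactly the concentration differences the
method correlates.

### Segment-wise alignment

Ionizable compounds shift with concentration and pH between fractions; a
rigid per-segment correction is applied before bucketing when requested.
The axis is cut into fixed-width segments (default 0.10 ppm).  For each
segment the integer-point shift `s ∈ [−max_shift, +max_shift]` (default
0.02 ppm) maximizing the cross-correlation of the *first differences* of
target and reference is applied; first differences make the score sensitive
to peak positions rather than baseline.  Vacated edge points are filled by
linear interpolation between the surviving boundary values, which bounds
the intensity perturbation per segment.  Ties break to the smaller |s|,
then to the negative shift — fully deterministic.  Segments shorter than
3 points are skipped with a warning.

Reference policies: `pairwise-sequential` (default) aligns spectrum k to
the *already-aligned* spectrum k−1 in elution order, so corrections
propagate down the series; neighboring fractions share composition, which
a single global reference does not guarantee (different compounds can
resonate at the same δH in different fractions).  The output therefore
depends on elution order — documented behavior, not an error.
`fixed-reference` aligns all spectra to one chosen index.  Shifts are
integer grid points; no sub-point interpolation (a deliberate non-goal,
as is non-rigid warping).

## 3. The mixture simulator

The generator emulates a fractionation study with known ground truth, so
detection can be scored.

- **Elution**: compound amounts spread over fractions as a discretized
  Gaussian (center, width in fraction units), renormalized so column sums
  equal amounts exactly (mass balance, recovery 1).  A profile losing
  > 1 % of its continuous mass outside the collected range is rejected.
  Smooth overlapping Gaussians are the right abstraction for pooled
  counter-current fractions; no partition-coefficient physics is modelled.
- **Activity**: the radical-scavenging load of fraction i is
  `p_i = Σ_k conc_ik / EC_k`, where `EC_k` is the concentration at which
  compound k alone reaches half-saturation (∞ for inactive).  Mean
  inhibition is `100 · p_i / (1 + p_i)` — a Hill form with coefficient 1:
  additive in load at low concentration, saturating near 100 % where the
  concentration–activity relationship (and hence correlation) breaks down.
  Replicates add truncated Gaussian noise and are summarized as mean ± SD.
  A compound is labelled *active* iff its solo inhibition at the reference
  concentration (default 1.0 concentration unit) exceeds 50 %, i.e.
  `EC < 1`.
- **Spectra**: Lorentzian multiplets from explicit peak lists (no
  J-coupling engine — sufficient for correlation-level behavior), line
  FWHM ~0.003 ppm on a 0.2–10 ppm axis at 0.001 ppm/point.  Tails are
  evaluated to ±200 FWHM (< 0.2 % truncated area).  Chemical-shift jitter
  is one Gaussian draw per (fraction, compound) — all peaks of a compound
  move together, as for concentration-dependent shifts of ionizable
  compounds.  Additive Gaussian noise models thermal noise.
- **Solubility dropout**: `nmr_solubility_cap` truncates concentrations
  for spectral synthesis *only*; the bioassay uses the full amounts.  A
  saturated NMR sample shows a nearly constant signal while the assay
  response varies — the NMR/bioassay inconsistency that turns a strong
  scavenger into a wrong call.
- **Determinism**: every stochastic element (jitter, noise, replicates,
  preset geometry) derives from the design seed through fixed, purpose-keyed
  substreams; the same design reproduces bit-identical outputs.

### Presets

- `artfrct` — 10 compounds (5 active EC 0.45–0.8, 5 inactive) in 12
  fractions.  Actives ramp up together toward the late fractions and
  inactives concentrate early, giving the inhibition series real variance
  (0–~75 %, below the saturation plateau); one active carries a solubility
  cap.
- `artextr` — 59 compounds in 69 fractions, 20 active / 39 inactive
  (8 of the inactives get weak finite ECs of 30–300, far above the 50 %
  rule).  With `confounders=True` (default) elution centers are drawn
  across the whole run, so actives and inactives co-elute freely — the
  realistic regime.  With `confounders=False` the 20 actives elute as one
  broad overlapping band (centers 34–42, width 8) and every inactive
  elutes well clear of it; active ECs (0.45–0.95) keep the peak load
  around 1.5–2 so the response tops out near 60 %, comfortably below the
  plateau.  In that controlled regime every active's concentration profile
  tracks the response (r ≈ 0.89) and no inactive's does — the regime in
  which correlation-based detection *should* recover everything, which is
  exactly what the acceptance check asserts.
- `coelution-fp` — an inactive compound sharing its elution (center,
  width) with a strong active: their concentration columns are
  proportional (r = 1.0), so the inactive inherits the active's deep-red
  resonances.  The false-positive mechanism.
- `overshadow-fn` — a genuinely active compound at ~5 % of the load of a
  stronger active eluting 4 fractions away: the response peaks where the
  strong compound does, the weak one's profile decorrelates (r ≈ 0.2) and
  it is called inactive despite real potency.  The false-negative
  mechanism.
- `misalignment` — the controlled `artextr` geometry with 0.01 ppm
  per-fraction jitter and noise on, used to quantify the alignment
  benefit.

What the simulator does **not** model: real multiplet structure and
J-coupling, baseline/phase artifacts, pH-dependent *systematic* (as
opposed to random) shift trajectories, relaxation-weighted intensities,
and the actual partition chemistry of counter-current separation.  Passing
tests on simulated data therefore demonstrate the statistical machinery
and its failure modes under controlled conditions; they do not certify
performance on any particular real extract.

## 4. Detection calls and scoring

The pseudospectrum flags variables; studies tally compounds.  The decision
rule is an explicit operationalization of what is otherwise expert reading
of the colored plot plus STOCSY — every call carries per-bucket evidence
so a human can override it:

1. Each diagnostic peak of a library compound is matched to the kept
   bucket with the largest |covariance| within `ppm_tolerance` (default:
   one bucket width) of its reference position.  Peaks inside excluded
   regions match nothing.
2. *Detected*: at least `min_peak_fraction` (default 0.5) of the peaks lie
   in buckets with |covariance| above a noise floor (default: 3 × 1.4826 ×
   MAD of all covariances; on noise-free data this degenerates to "any
   nonzero covariance").
3. *Predicted active*: at least that same fraction of the supporting
   buckets are deep red — `r ≥ high_corr_threshold` (default 0.8, a
   required, logged parameter) with positive covariance.
4. *Predicted inactive*: detected, with median supporting r below
   `low_corr_threshold` (default 0.5).  Anything between is an ambiguous
   call, reported as inactive with a flag.

Raising the deep-red threshold can only shrink the active set (asserted
monotonicity).  Scoring follows ground-truthed-study bookkeeping: overall
success = correct / identified; active success = correctly-called actives /
all true actives, so undetected actives stay in the denominator without
being counted as false negatives (they were never characterized in terms
of their correlation with activity).  Rates are exact rational arithmetic
rendered to one decimal place, half-up.

The per-compound concentration/activity Pearson audit (the "integration
table" diagnostic) explains calls after the fact: a high-r inactive
reveals co-elution, a near-zero-r active reveals overshadowing or
solubility dropout; a constant concentration column (r = 0 by the
zero-variance policy) flags the wide-distribution false-positive risk.

## 5. Rendering

Pseudospectra are drawn with the field's convention: chemical shift
decreasing left to right, covariance as line height (positive peaks =
positive covariance), correlation as line color with fixed limits.  Two
color encodings are provided because published figures are ambiguous at
print resolution: `magnitude` (|r| ∈ [0, 1], blue → red, default) and
`signed` (r ∈ [−1, 1], diverging).  Rendering never mutates its inputs.

## 6. Problem sizes and numeric choices

- Simulated axis: 9 801 points (0.2–10 ppm at 0.001 ppm); 69-fraction
  presets synthesize in ~1 s (a shared-signature fast path handles the
  jitter-free case).
- The estimator-vs-oracle acceptance check uses 200 random matrices with
  n ∈ [3, 60], p ∈ [10, 5000], agreement to 1e−10 absolute; the
  acceptance *script* uses 60 matrices with p ≤ 2000, reporting the
  observed maximum error.  The alignment-benefit comparison uses 10 seeds
  in the test suite and 6 in the script.  These sizes were chosen as the
  smallest that exercise every code path at study scale.
- Bucket assignment adds a 1e−9 relative epsilon before flooring so points
  on exact bucket boundaries land deterministically; elution weights below
  10⁻¹⁵ of the profile maximum are zeroed so near-delta profiles occupy a
  single fraction.
- Mass balance is exact to renormalization (float rounding ≤ 1e−12
  relative); tests assert at that tolerance.

## 7. Known limitations

- Compound calls depend on the operator-set `high_corr_threshold`; 0.8 is
  a sensible default for noise-free to moderately noisy data but has no
  universal justification — which is why it is a required, logged
  parameter and the report retains bucket-level evidence.
- Pairwise-sequential alignment accumulates the first fraction's shift
  state; absolute positions can end one to two grid points from the
  library's reference values (the detection tolerance absorbs this).
- The JCAMP-DX adapter reads AFFN/XYPOINTS tables only; compressed
  (SQZ/DIF/DUP) encodings are rejected with a clear message.  The
  delimited matrix is the canonical interchange format.
- Partial-HetCA output is descriptive; no automatic reconciliation of
  conflicting window calls is attempted.
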