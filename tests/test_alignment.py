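"""Segment-wise alignment: shift search, edge filling, chain behavior."""

import warnings

import numpy as np
import pytest

import hetcakit as hk
from hetcakit.alignment import _best_shift


def exhaustive_best_shift(d_ref, d_tar, max_shift):
    """Independent brute-force search over every shift in the window."""
    best = None
    for s in range(-max_shift, max_shift + 1):
        tot = 0.0
        for i in range(d_ref.size):
            j = i - s
            if 0 <= j < d_tar.size:
                tot += d_ref[i] * d_tar[j]
        key = (-tot, abs(s), s)
        if best is None or key < best[0]:
            best = (key, s)
    return best[1]


def lorentzian(x, center, gamma=0.02):
    return gamma / ((x - center) ** 2 + gamma**2)


@pytest.fixture
def fine_axis():
    return hk.PpmAxis(np.linspace(10.0, 0.0, 1001))  # 0.01 ppm/pt


class TestShiftSearch:
    @pytest.mark.parametrize("case", range(25))
    def test_agrees_with_exhaustive_oracle(self, case):
        rng = np.random.default_rng(900 + case)
        x = np.arange(200, dtype=float)
        ref = lorentzian(x, rng.uniform(60, 140), rng.uniform(2, 6))
        d = int(rng.integers(-8, 9))
        tar = np.roll(ref, d)
        dr, dt = np.diff(ref), np.diff(tar)
        assert _best_shift(dr, dt, 10) == exhaustive_best_shift(dr, dt, 10)

    def test_ties_prefer_small_then_negative_shift(self):
        d = np.zeros(20)
        assert _best_shift(d, d, 5) == 0  # all-zero scores tie at every lag


class TestAlignPair:
    def test_identity_input_bit_identical(self, fine_axis):
        ppm = fine_axis.values
        ref = hk.Spectrum("r", lorentzian(ppm, 5.55))
        plan = hk.AlignmentPlan(segment_width=1.0, max_shift=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, shifts = hk.align_pair(ref, ref, plan, fine_axis)
        assert np.all(shifts == 0)
        np.testing.assert_array_equal(out.intensities, ref.intensities)

    def test_displaced_peak_recovered(self, fine_axis):
        ppm = fine_axis.values
        ref = hk.Spectrum("r", lorentzian(ppm, 5.55))
        tar = hk.Spectrum("t", lorentzian(ppm, 5.55 + 5 * 0.01))
        plan = hk.AlignmentPlan(segment_width=1.0, max_shift=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, shifts = hk.align_pair(tar, ref, plan, fine_axis)
        nz = shifts[shifts != 0]
        assert list(nz) == [5]  # one segment corrected by 5 points
        assert ppm[np.argmax(out.intensities)] == pytest.approx(5.55)

    def test_displacement_beyond_window_clamps_at_max_shift(self, fine_axis):
        ppm = fine_axis.values
        ref = hk.Spectrum("r", lorentzian(ppm, 5.55))
        tar = hk.Spectrum("t", lorentzian(ppm, 5.55 + 8 * 0.01))
        plan = hk.AlignmentPlan(segment_width=1.0, max_shift=0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, shifts = hk.align_pair(tar, ref, plan, fine_axis)
        assert np.max(np.abs(shifts)) == 5  # best in-window shift

    def test_short_trailing_segment_skipped_with_warning(self, fine_axis):
        ppm = fine_axis.values
        ref = hk.Spectrum("r", lorentzian(ppm, 5.55))
        plan = hk.AlignmentPlan(segment_width=1.0, max_shift=0.1)
        with pytest.warns(UserWarning, match="skipped"):
            hk.align_pair(ref, ref, plan, fine_axis)  # 1001 pts -> 1-pt tail

    def test_intensity_change_bounded_by_edge_fill(self, fine_axis):
        ppm = fine_axis.values
        rng = np.random.default_rng(7)
        ref = hk.Spectrum("r", lorentzian(ppm, 5.55) + 0.01 * rng.random(ppm.size))
        tar = hk.Spectrum("t", lorentzian(ppm, 5.58) + 0.01 * rng.random(ppm.size))
        plan = hk.AlignmentPlan(segment_width=0.5, max_shift=0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, shifts = hk.align_pair(tar, ref, plan, fine_axis)
        # each segment moves at most max_shift points of intensity in/out
        max_pts = plan.max_shift_points(fine_axis)
        bound = np.abs(shifts).sum() * max(np.abs(tar.intensities)) * 2
        assert abs(out.intensities.sum() - tar.intensities.sum()) <= bound + 1e-9


class TestAlignSet:
    def test_identical_spectra_all_zero_shifts(self, fine_axis):
        ppm = fine_axis.values
        y = lorentzian(ppm, 4.55)
        s = hk.SpectrumSet(
            fine_axis, tuple(hk.Spectrum(f"f{k}", y.copy()) for k in range(4))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hk.align_set(s, hk.AlignmentPlan(segment_width=1.0, max_shift=0.1))
        assert np.all(res.shifts == 0)

    def test_cumulative_drift_corrected_incrementally(self, fine_axis):
        """Drift of +2 then +4 points: the chain recovers 2 more each step."""
        ppm = fine_axis.values
        spectra = tuple(
            hk.Spectrum(f"f{k}", lorentzian(ppm, 5.55 + 0.01 * d))
            for k, d in enumerate([0, 2, 4])
        )
        s = hk.SpectrumSet(fine_axis, spectra)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hk.align_set(s, hk.AlignmentPlan(segment_width=1.0, max_shift=0.05))
        per_spec = res.shifts.sum(axis=1)
        assert list(per_spec) == [0, 2, 4]  # cumulative correction, step 2
        for sp in res.aligned.spectra:
            assert ppm[np.argmax(sp.intensities)] == pytest.approx(5.55)

    def test_reversed_order_gives_different_alignment(self, fine_axis):
        """Pairwise-sequential output depends on elution order (documented)."""
        ppm = fine_axis.values
        rng = np.random.default_rng(11)
        spectra = tuple(
            hk.Spectrum(
                f"f{k}",
                lorentzian(ppm, 5.53 + 0.01 * k) + lorentzian(ppm, 2.32 - 0.01 * k),
            )
            for k in range(3)
        )
        fwd = hk.SpectrumSet(fine_axis, spectra)
        rev = hk.SpectrumSet(fine_axis, spectra[::-1])
        plan = hk.AlignmentPlan(segment_width=1.0, max_shift=0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_fwd = hk.align_set(fwd, plan)
            a_rev = hk.align_set(rev, plan)
        fwd_first = a_fwd.aligned.spectra[0].intensities
        rev_last = a_rev.aligned.spectra[-1].intensities  # same original spectrum
        assert not np.array_equal(fwd_first, rev_last)

    def test_fixed_reference_mode_and_bad_index(self, fine_axis):
        ppm = fine_axis.values
        s = hk.SpectrumSet(
            fine_axis,
            tuple(
                hk.Spectrum(f"f{k}", lorentzian(ppm, 5.55 + 0.01 * k))
                for k in range(3)
            ),
        )
        plan = hk.AlignmentPlan(
            segment_width=1.0, max_shift=0.05,
            reference_policy="fixed-reference", reference_index=9,
        )
        with pytest.raises(hk.ValidationError, match="out of range"):
            hk.align_set(s, plan)

    def test_jittered_simulation_apexes_realign_within_one_point(self):
        """Resolved peaks jittered below max_shift end up on a common grid
        position (±1 point) after alignment."""
        peaks = [2.05, 5.55, 8.05]
        comps = tuple(
            hk.CompoundSpec(f"c{k}", ((p, 0.003, 1.0),), np.inf, 4.5, 1.3, 1.0)
            for k, p in enumerate(peaks)
        )
        d = hk.MixtureDesign(compounds=comps, n_fractions=8, jitter_sd=0.005, seed=3)
        spectra, _, _ = hk.simulate(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hk.align_set(spectra, hk.AlignmentPlan())
        ppm = spectra.axis.values
        step = spectra.axis.resolution
        for p in peaks:
            win = (ppm > p - 0.05) & (ppm < p + 0.05)
            apices = [
                ppm[win][np.argmax(sp.intensities[win])]
                for sp in res.aligned.spectra
            ]
            pre = [ppm[win][np.argmax(sp.intensities[win])] for sp in spectra.spectra]
            assert np.ptp(apices) <= step * 1.001
            assert np.ptp(apices) <= np.ptp(pre)

    def test_shift_report_table_shape(self, fine_axis):
        ppm = fine_axis.values
        s = hk.SpectrumSet(
            fine_axis,
            tuple(
                hk.Spectrum(f"f{k}", lorentzian(ppm, 5.55 + 0.005 * k))
                for k in range(3)
            ),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hk.align_set(s, hk.AlignmentPlan(segment_width=1.0, max_shift=0.05))
        df = res.shift_table()
        assert set(df.columns) == {"fraction_id", "segment_lo", "segment_hi", "shift_points"}
        assert len(df) == 3 * res.shifts.shape[1]
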