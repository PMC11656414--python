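"""Mixture simulator: elution, activity model, spectra, presets."""

import numpy as np
import pytest

import hetcakit as hk


def solo_design(**overrides):
    defaults = dict(
        compounds=(
            hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.2, 6.0, 2.2, 1.0),
        ),
        n_fractions=12,
        seed=0,
    )
    defaults.update(overrides)
    return hk.MixtureDesign(**defaults)


class TestElution:
    def test_mass_balance_exact_on_random_designs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 40))
            comps = []
            for k in range(int(rng.integers(1, 8))):
                c = float(rng.uniform(n * 0.3, n * 0.7))
                w_max = min(c - 0.5, n + 0.5 - c) / 2.6  # keep tails collected
                comps.append(
                    hk.CompoundSpec(
                        f"c{k}",
                        ((1.0 + k, 0.003, 1.0),),
                        np.inf,
                        c,
                        float(rng.uniform(0.3, max(w_max, 0.31))),
                        float(rng.uniform(0.1, 5.0)),
                    )
                )
            comps = tuple(comps)
            d = hk.MixtureDesign(compounds=comps, n_fractions=n, seed=1)
            truth = hk.simulate_elution(d)
            amounts = np.array([c.amount for c in comps])
            np.testing.assert_allclose(
                truth.concentration.sum(axis=0), amounts, rtol=1e-12, atol=0
            )

    def test_delta_limit_all_mass_in_one_fraction(self):
        d = solo_design(
            compounds=(
                hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.2, 6.0, 1e-9, 2.5),
            )
        )
        truth = hk.simulate_elution(d)
        col = truth.concentration[:, 0]
        assert col[5] == 2.5 and np.count_nonzero(col) == 1

    def test_center_outside_range_rejected(self):
        d = solo_design(
            compounds=(
                hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.2, 20.0, 2.0, 1.0),
            )
        )
        with pytest.raises(hk.ValidationError, match="mass"):
            hk.simulate_elution(d)

    def test_identical_elution_parameters_give_unit_correlation(self):
        comps = (
            hk.CompoundSpec("a", ((2.0, 0.003, 1.0),), 0.2, 6.0, 1.5, 1.0),
            hk.CompoundSpec("b", ((7.0, 0.003, 1.0),), np.inf, 6.0, 1.5, 0.3),
        )
        d = hk.MixtureDesign(compounds=comps, n_fractions=12, seed=0)
        truth = hk.simulate_elution(d)
        r = np.corrcoef(truth.concentration[:, 0], truth.concentration[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


class TestActivity:
    def test_zero_concentration_zero_inhibition(self):
        d = solo_design(
            compounds=(
                hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.2, 6.0, 2.2, 0.0),
            )
        )
        truth = hk.simulate_elution(d)
        act = hk.simulate_activity(truth, d)
        np.testing.assert_array_equal(act.mean_inhibition, 0.0)

    def test_half_saturation_at_ec(self):
        """A single compound at exactly its EC inhibits 50.0 % (noise off)."""
        comps = (hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.4, 2.0, 1e-9, 0.4),)
        d = hk.MixtureDesign(compounds=comps, n_fractions=3, seed=0)
        truth = hk.simulate_elution(d)  # all mass -> fraction 2, conc = EC
        act = hk.simulate_activity(truth, d)
        assert act.mean_inhibition[1] == pytest.approx(50.0, abs=1e-9)

    def test_plateau_regime_closed_form(self):
        """Load p = 9 sits on the >80 % plateau: inhibition = 90.0 %."""
        comps = (hk.CompoundSpec("solo", ((5.0, 0.003, 1.0),), 0.1, 2.0, 1e-9, 0.9),)
        d = hk.MixtureDesign(compounds=comps, n_fractions=3, seed=0)
        truth = hk.simulate_elution(d)
        act = hk.simulate_activity(truth, d)
        assert act.mean_inhibition[1] == pytest.approx(90.0, abs=1e-9)

    def test_activity_monotone_in_concentration(self):
        d = solo_design()
        truth = hk.simulate_elution(d)
        act = hk.simulate_activity(truth, d)
        order = np.argsort(truth.concentration[:, 0])
        assert np.all(np.diff(act.mean_inhibition[order]) >= 0)

    def test_nonpositive_ec_rejected(self):
        with pytest.raises(hk.ValidationError, match="EC"):
            hk.CompoundSpec("bad", ((5.0, 0.003, 1.0),), 0.0, 6.0, 2.0, 1.0)

    def test_replicate_noise_summarized(self):
        d = solo_design(activity_noise_sd=2.0, activity_replicates=3)
        truth = hk.simulate_elution(d)
        act = hk.simulate_activity(truth, d)
        assert np.all(act.sd >= 0) and np.any(act.sd > 0)
        assert np.all(act.n_replicates == 3)


class TestSpectra:
    def test_peak_integral_proportional_to_concentration(self):
        d = solo_design()
        spectra, act, truth = hk.simulate(d)
        ppm = spectra.axis.values
        win = (ppm > 4.9) & (ppm < 5.1)
        integrals = spectra.matrix[:, win].sum(axis=1)
        r = np.corrcoef(integrals, truth.concentration[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_jitter_contract_apex_variance(self):
        apexes = {}
        for jsd in (0.0, 0.01):
            d = solo_design(jitter_sd=jsd, seed=4)
            spectra, _, truth = hk.simulate(d)
            ppm = spectra.axis.values
            win = (ppm > 4.8) & (ppm < 5.2)
            keep = truth.concentration[:, 0] > 0.01
            apexes[jsd] = np.array(
                [ppm[win][np.argmax(row[win])] for row in spectra.matrix[keep]]
            )
        assert np.ptp(apexes[0.0]) == 0.0
        assert np.ptp(apexes[0.01]) > 0.0

    def test_peak_outside_axis_rejected(self):
        d = solo_design(
            compounds=(
                hk.CompoundSpec("solo", ((11.0, 0.003, 1.0),), 0.2, 6.0, 2.2, 1.0),
            )
        )
        truth = hk.simulate_elution(d)
        with pytest.raises(hk.ValidationError, match="outside axis"):
            hk.simulate_spectra(truth, d)

    def test_solubility_cap_decorrelates_nmr_from_activity(self):
        """The saturated-sample mechanism: capping concentrations for the
        spectra only drives the peak's activity correlation from ~1 down
        below the deep-red threshold, while the bioassay still sees the
        full amount."""
        rs = {}
        for cap in (None, 0.008):
            comps = (
                hk.CompoundSpec(
                    "solo", ((5.0, 0.003, 1.0),), 0.2, 6.0, 2.2, 1.0,
                    nmr_solubility_cap=cap,
                ),
            )
            d = hk.MixtureDesign(compounds=comps, n_fractions=12, seed=0)
            spectra, act, truth = hk.simulate(d)
            b = hk.bucket(hk.apply_exclusions(spectra), 0.01)
            ps = hk.hetca(b, act)
            rs[cap] = ps.correlation[b.nearest_bucket(5.0)]
        assert rs[None] > 0.95
        assert rs[0.008] < hk.CorrelationOptions().high_corr_threshold

    def test_same_seed_bit_identical_outputs(self):
        d = hk.preset("artfrct", seed=9)
        s1, a1, _ = hk.simulate(d)
        s2, a2, _ = hk.simulate(d)
        np.testing.assert_array_equal(s1.matrix, s2.matrix)
        np.testing.assert_array_equal(a1.mean_inhibition, a2.mean_inhibition)
        np.testing.assert_array_equal(a1.sd, a2.sd)


class TestPresets:
    def test_artfrct_dimensions(self):
        d = hk.preset("artfrct")
        assert len(d.compounds) == 10 and d.n_fractions == 12

    def test_artextr_dimensions_and_label_split(self):
        d = hk.preset("artextr")
        assert len(d.compounds) == 59 and d.n_fractions == 69
        truth = hk.simulate_elution(d)
        n_active = sum(truth.active_labels.values())
        assert n_active == 20 and len(truth.active_labels) - n_active == 39

    def test_coelution_preset_has_correlated_inactive(self):
        d = hk.preset("coelution-fp")
        truth = hk.simulate_elution(d)
        active = [n for n, v in truth.active_labels.items() if v]
        inactive = [n for n, v in truth.active_labels.items() if not v]
        best = max(
            np.corrcoef(
                truth.concentration_of(a), truth.concentration_of(i)
            )[0, 1]
            for a in active
            for i in inactive
        )
        assert best >= 0.9

    def test_unknown_preset_lists_names(self):
        with pytest.raises(hk.ValidationError, match="artextr"):
            hk.preset("nope")

    def test_misalignment_preset_has_jitter(self):
        d = hk.preset("misalignment")
        assert d.jitter_sd == pytest.approx(0.01)
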