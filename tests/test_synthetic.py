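import numpy as np
import pytest

from serscreen.evaluation import CohortEntry, LabeledCohort, empirical_roc
from serscreen.scoring import BandSet, score_sample
from serscreen.synthetic import (
    CalibrationFit,
    ConcentrationMixture,
    SyntheticConfig,
    baseline_function,
    fit_calibration,
    simulate_cohort,
    simulate_spectrum,
)


def make_cohort(scores, concs, limit=600.0):
    entries = [
        CohortEntry(str(i), float(s), float(c))
        for i, (s, c) in enumerate(zip(scores, concs))
    ]
    return LabeledCohort(entries, regulatory_limit=limit)


class TestSimulateSpectrum:
    def test_blank_noiseless_equals_baseline(self):
        cfg = SyntheticConfig(noise_sd=0.0, n_interference_peaks=0)
        s, truth = simulate_spectrum(0.0, cfg, seed=1)
        expected = baseline_function(s.wavenumbers, cfg.baseline_coeffs)
        assert np.allclose(s.intensities, expected, atol=1e-12)
        assert truth.peaks == []

    def test_forced_monomer_closed_form(self):
        # phi = 1: monomer bands only, apex = gain * conc on top of baseline
        cfg = SyntheticConfig(noise_sd=0.0, n_interference_peaks=0, shift_sd=0.0)
        conc = 600.0
        s, truth = simulate_spectrum(conc, cfg, seed=2, monomer_fraction=1.0)
        base = baseline_function(s.wavenumbers, cfg.baseline_coeffs)
        resid = s.intensities - base
        b = BandSet()
        naph = (s.wavenumbers >= b.monomer_naphthenic.lower) & (
            s.wavenumbers <= b.monomer_naphthenic.upper
        )
        assert resid[naph].max() == pytest.approx(cfg.monomer_gain * conc, rel=0.02)
        # dimer windows contain baseline only
        for band in (b.dimer_naphthenic, b.dimer_carboxylic):
            m = (s.wavenumbers >= band.lower) & (s.wavenumbers <= band.upper)
            assert resid[m].max() < 0.02 * cfg.monomer_gain * conc

    def test_peak_centers_stay_inside_windows(self):
        b = BandSet()
        windows = {
            "monomer_naphthenic": b.monomer_naphthenic,
            "monomer_carboxylic": b.monomer_carboxylic,
            "dimer_naphthenic": b.dimer_naphthenic,
            "dimer_carboxylic": b.dimer_carboxylic,
        }
        for seed in range(50):
            _, truth = simulate_spectrum(700.0, seed=seed)
            for p in truth.peaks:
                if p.label in windows:
                    w = windows[p.label]
                    assert w.lower <= p.center <= w.upper

    def test_interference_avoids_analyte_windows(self):
        b = BandSet()
        for seed in range(30):
            _, truth = simulate_spectrum(0.0, seed=seed)
            for p in truth.peaks:
                assert p.label == "interference"
                for band in (
                    b.monomer_naphthenic,
                    b.monomer_carboxylic,
                    b.dimer_naphthenic,
                    b.dimer_carboxylic,
                ):
                    assert not (band.lower <= p.center <= band.upper)

    def test_deterministic_given_seed(self):
        s1, _ = simulate_spectrum(400.0, seed=123)
        s2, _ = simulate_spectrum(400.0, seed=123)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectrum(-1.0)


class TestDoseResponse:
    def test_mean_sum_score_monotone_in_concentration(self):
        concs = [0, 100, 200, 300, 400, 500, 600, 700, 800]
        means, sems = [], []
        for conc in concs:
            sums = []
            for seed in range(100):
                s, _ = simulate_spectrum(float(conc), seed=10_000 + seed)
                sums.append(score_sample(s).sum_score)
            sums = np.asarray(sums)
            means.append(sums.mean())
            sems.append(sums.std(ddof=1) / np.sqrt(len(sums)))
        for i in range(len(concs) - 1):
            # non-decreasing within sampling error of the seeded means
            assert means[i + 1] >= means[i] - 3 * np.hypot(sems[i], sems[i + 1])

    def test_higher_dose_scores_higher(self):
        hi = [score_sample(simulate_spectrum(500.0, seed=s)[0]).sum_score for s in range(200)]
        lo = [score_sample(simulate_spectrum(50.0, seed=s)[0]).sum_score for s in range(200)]
        assert np.mean(hi) > np.mean(lo)

    def test_dimer_silent_below_onset(self):
        cfg = SyntheticConfig()
        n_zero = 0
        n = 100
        for seed in range(n):
            s, _ = simulate_spectrum(200.0, cfg, seed=seed)  # < dimer_onset_ppm = 350
            if score_sample(s).ratio_dimer == 0.0:
                n_zero += 1
        assert n_zero >= 0.99 * n


class TestSimulateCohort:
    def test_reproducible_for_seed(self):
        a = simulate_cohort(15, seed=5)
        b = simulate_cohort(15, seed=5)
        assert [e.sum_score for e in a.cohort.entries] == [e.sum_score for e in b.cohort.entries]
        assert [e.hplc_ppm for e in a.cohort.entries] == [e.hplc_ppm for e in b.cohort.entries]

    def test_degenerate_all_blank_mixture(self):
        sim = simulate_cohort(10, ConcentrationMixture(zero_weight=1.0), seed=3)
        assert all(e.hplc_ppm == 0.0 for e in sim.cohort.entries)

    def test_invalid_mixture_weight(self):
        with pytest.raises(ValueError):
            ConcentrationMixture(zero_weight=1.5)

    def test_end_to_end_auc_recovers_true_labels(self):
        sim = simulate_cohort(2000, seed=424242)
        roc = empirical_roc(sim.cohort)
        assert roc.n_pos >= 20
        assert roc.auc > 0.9


class TestCalibration:
    def test_exact_line_recovered(self):
        ppm = np.linspace(380, 820, 12)
        cohort = make_cohort(0.01 * ppm + 0.3, ppm)
        fit = fit_calibration(cohort, blank_scores=np.array([0.1, 0.2, 0.3]))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.01, abs=1e-9)

    def test_zero_blank_sd_gives_zero_limits(self):
        ppm = np.linspace(380, 820, 8)
        cohort = make_cohort(0.01 * ppm, ppm)
        fit = fit_calibration(cohort, blank_scores=np.array([0.5, 0.5, 0.5]))
        assert fit.lod_ppm == 0.0 and fit.loq_ppm == 0.0

    def test_lod_matches_convention_closed_form(self, rng):
        slope, blank_sd = 0.01, 0.3
        ppm = np.linspace(380, 820, 30)
        scores = slope * ppm + rng.normal(0, 0.05, len(ppm))
        blanks = rng.normal(0, blank_sd, 200)
        fit = fit_calibration(make_cohort(scores, ppm), blank_scores=blanks)
        assert fit.lod_ppm == pytest.approx(3.3 * blank_sd / slope, rel=0.15)
        assert fit.loq_ppm == pytest.approx(10 * blank_sd / slope, rel=0.15)
        assert fit.loq_ppm >= fit.lod_ppm

    def test_insufficient_points_raise(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [0.0, 100.0, 200.0])
        with pytest.raises(ValueError):
            fit_calibration(cohort, range_ppm=(380.0, 820.0), blank_scores=np.zeros(5))
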