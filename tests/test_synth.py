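"""Generators: vowel audio, lip video, feature bank, cohort, sensor projection."""

import numpy as np
import pytest
from scipy import signal as sg

from silenttrack.errors import InvalidParameterError
from silenttrack.types import FeaturePlan
from silenttrack import synth
from silenttrack.coherence import COMBINED_BAND, band_average, coherence_map, multitaper_spectra
from silenttrack.pipeline import cohort_coherence, cohort_index_maps
from silenttrack.config import PipelineConfig

from conftest import VOWEL_DURATION_S, VOWEL_F0, VOWEL_FORMANTS


class TestVowelAudio:
    def test_length_matches_duration(self, vowel_audio):
        assert vowel_audio.samples.size == int(VOWEL_DURATION_S * 48000)

    def test_spectrum_peaks_at_planted_formants(self):
        # f0 = 100 Hz puts harmonics exactly on the planted formants, so the
        # voiced (line) spectrum peaks right at the resonances
        plans = [FeaturePlan.constant(f, 2.0) for f in VOWEL_FORMANTS]
        audio = synth.synthesize_vowel_audio(plans, FeaturePlan.constant(100.0, 2.0), 2.0)
        f, p = sg.welch(audio.samples, fs=48000, nperseg=4096)
        for target in VOWEL_FORMANTS[:3]:
            m = (f > target - 200) & (f < target + 200)
            peak = f[m][np.argmax(p[m])]
            assert abs(peak - target) <= 50.0

    def test_autocorrelation_peak_at_pitch_period(self, vowel_audio):
        x = vowel_audio.samples
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        expected_lag = 48000 / VOWEL_F0
        lo, hi = int(0.8 * expected_lag), int(1.2 * expected_lag)
        lag = lo + np.argmax(ac[lo:hi])
        assert abs(lag - expected_lag) <= 2

    def test_rejects_formant_at_nyquist(self):
        plans = [FeaturePlan.constant(f, 1.0) for f in (500, 1500, 25000)]
        with pytest.raises(InvalidParameterError):
            synth.synthesize_vowel_audio(plans, FeaturePlan.constant(120, 1.0), 1.0, 48000)

    def test_rejects_nonpositive_duration(self):
        plans = [FeaturePlan.constant(f, 1.0) for f in (500, 1500, 2500)]
        with pytest.raises(InvalidParameterError):
            synth.synthesize_vowel_audio(plans, FeaturePlan.constant(120, 1.0), 0.0)


class TestLipVideo:
    def test_constant_area_pixel_count(self):
        vid = synth.synthesize_lip_video(FeaturePlan.constant(2000.0, 1.0), fps=50)
        assert vid.frames.shape[0] == 50
        counts = (vid.frames > 0.5).sum(axis=(1, 2))
        assert np.all(np.abs(counts - 2000) / 2000 < 0.05)

    def test_zero_area_is_dark(self):
        vid = synth.synthesize_lip_video(FeaturePlan.constant(0.0, 0.5), fps=50)
        assert np.all(vid.frames == 0)

    def test_sinusoidal_aperture_has_planted_spectral_peak(self):
        t = np.arange(0, 5.02, 0.02)
        plan = FeaturePlan(t, 1500 + 800 * np.sin(2 * np.pi * 3 * t))
        vid = synth.synthesize_lip_video(plan, fps=50)
        areas = (vid.frames > 0.5).sum(axis=(1, 2)).astype(float)
        f, p = sg.periodogram(areas - areas.mean(), fs=50)
        assert abs(f[np.argmax(p)] - 3.0) < 0.3

    def test_oversized_aperture_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.synthesize_lip_video(FeaturePlan.constant(1e6, 1.0), frame_size=(32, 32))


class TestFeatureBank:
    def test_identity_correlation_near_zero(self):
        bank = synth.generate_feature_bank(300.0, seed=0)
        x = np.stack([t.samples for t in bank.values()])
        r = np.corrcoef(x)
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_requested_correlation_recovered(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.5
        bank = synth.generate_feature_bank(300.0, cross_corr=c, seed=1)
        r = np.corrcoef(bank["lip"].samples, bank["envelope"].samples)[0, 1]
        assert abs(r - 0.5) < 0.1

    def test_covariance_converges_at_long_duration(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.4
        c[2, 3] = c[3, 2] = -0.3
        bank = synth.generate_feature_bank(600.0, cross_corr=c, seed=2)
        x = np.stack([t.samples for t in bank.values()])
        assert np.max(np.abs(np.corrcoef(x) - c)) < 0.05

    def test_standardized_and_deterministic(self):
        a = synth.generate_feature_bank(60.0, seed=9)
        b = synth.generate_feature_bank(60.0, seed=9)
        for name in a:
            assert np.array_equal(a[name].samples, b[name].samples)
            assert abs(a[name].samples.mean()) < 1e-12
            assert abs(a[name].samples.std() - 1) < 1e-12

    def test_non_psd_matrix_rejected(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 1.5
        with pytest.raises(InvalidParameterError):
            synth.generate_feature_bank(60.0, cross_corr=c, seed=0)


class TestGridAndForward:
    def test_grid_has_all_regions(self):
        grid = synth.build_grid((6, 6, 6), 10.0)
        assert set(grid.region_labels) == {"occipital", "cingulate", "other"}
        assert grid.n_voxels == 216

    def test_projection_is_linear_in_sources(self):
        grid = synth.build_grid((4, 4, 4))
        fwd = synth.make_forward_model(grid, n_sensors=16, seed=0)
        src = np.zeros((64, 100))
        src[10] = np.sin(np.arange(100) / 5)
        rec = synth.project_to_sensors(fwd, src, 0.0)
        expected = np.outer(fwd.leadfield[:, 10], src[10])
        assert np.allclose(rec.data, expected)
        rec2 = synth.project_to_sensors(fwd, 2 * src, 0.0)
        assert np.allclose(rec2.data, 2 * rec.data)

    def test_pure_noise_sd(self):
        grid = synth.build_grid((4, 4, 4))
        fwd = synth.make_forward_model(grid, n_sensors=16, seed=0)
        rec = synth.project_to_sensors(fwd, np.zeros((64, 20000)), 0.7, seed=3)
        assert abs(rec.data.std() - 0.7) / 0.7 < 0.1

    def test_dimension_mismatch_rejected(self):
        grid = synth.build_grid((4, 4, 4))
        fwd = synth.make_forward_model(grid, n_sensors=16, seed=0)
        with pytest.raises(InvalidParameterError):
            synth.project_to_sensors(fwd, np.zeros((10, 100)), 0.0)


class TestCohort:
    def test_determinism(self):
        kw = dict(n_subjects=4, grid=synth.build_grid((3, 3, 3)),
                  n_trials_per_condition=5, seed=42)
        a = synth.simulate_cohort(**kw)
        b = synth.simulate_cohort(**kw)
        assert np.array_equal(a.ages, b.ages)
        for key in a.trials:
            assert np.array_equal(a.trials[key].data, b.trials[key].data)

    def test_every_subject_has_both_conditions_and_age_range(self):
        cohort = synth.simulate_cohort(
            5, 20, 60, grid=synth.build_grid((3, 3, 3)), n_trials_per_condition=4, seed=0
        )
        assert np.all((cohort.ages >= 20) & (cohort.ages <= 60))
        for sid in cohort.subject_ids:
            assert (sid, "natural") in cohort.trials
            assert (sid, "reversed") in cohort.trials
            assert cohort.trials[(sid, "natural")].n_trials == 4

    def test_zero_coupling_coherence_below_chance_level(self):
        """With no planted coupling, grand-mean 1-7 Hz coherence must sit at
        the chance level implied by the taper x trial count (Monte-Carlo
        null built from independent surrogate data)."""
        cohort = synth.simulate_cohort(
            4, coupling=synth.CouplingModel.zero(), grid=synth.build_grid((3, 3, 3)),
            n_trials_per_condition=20, seed=7,
        )
        cfg = PipelineConfig(grid_shape=(3, 3, 3), n_trials_per_condition=20)
        maps = cohort_coherence(cohort, cfg, features=("envelope",))
        grand = np.mean(
            [band_average(maps[(s, "envelope", "natural")], COMBINED_BAND)
             for s in cohort.subject_ids]
        )
        # null distribution: same estimator on independent white series
        rng = np.random.default_rng(0)
        nulls = []
        from silenttrack.types import TrialSet
        for _ in range(20):
            x = rng.standard_normal((20, 1, 300))
            y = rng.standard_normal((20, 300))
            cs = multitaper_spectra(TrialSet(x, condition="natural"), y)
            nulls.append(band_average(coherence_map(cs), COMBINED_BAND)[0])
        assert grand < np.mean(nulls) + 3 * np.std(nulls)

    def test_planted_age_slope_yields_negative_index_correlation(self):
        """End-to-end: a negative natural-formant age slope must produce a
        negative correlation between age and the occipital formant index."""
        grid = synth.build_grid((3, 3, 3))
        coupling = synth.CouplingModel(
            gains={
                ("formant", "occipital", "natural"): (0.24, -0.0032),
                ("formant", "occipital", "reversed"): (0.08, 0.0),
            }
        )
        cohort = synth.simulate_cohort(
            12, coupling=coupling, grid=grid, n_trials_per_condition=20, seed=3,
            features=("formant",),
        )
        cfg = PipelineConfig(grid_shape=(3, 3, 3), n_trials_per_condition=20,
                             features=("formant",))
        maps = cohort_coherence(cohort, cfg, features=("formant",))
        idx = cohort_index_maps(maps, cohort.subject_ids, ("formant",))["formant"]
        occ = grid.region_mask("occipital")
        r = np.corrcoef(cohort.ages, idx[:, occ].mean(axis=1))[0, 1]
        assert r < -0.3

    def test_planted_gain_slope_recovered_by_regression(self):
        """Regressing the planted per-subject gains on age recovers the
        configured slope (the clip at zero never binds in this range)."""
        coupling = synth.CouplingModel.headline()
        a0, a1 = coupling.gains[("formant", "occipital", "natural")]
        rng = np.random.default_rng(0)
        ages = rng.uniform(19, 63, 50)
        gains = np.array([coupling.gain("formant", "occipital", "natural", a) for a in ages])
        slope = np.polyfit(ages, gains, 1)[0]
        assert abs(slope - a1) < 1e-12

    def test_grid_missing_region_rejected(self):
        grid = synth.build_grid((3, 3, 3))
        grid.region_labels[:] = "other"
        with pytest.raises(InvalidParameterError):
            synth.simulate_cohort(3, grid=grid, n_trials_per_condition=2, seed=0)
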