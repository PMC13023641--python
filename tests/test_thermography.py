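import numpy as np
import pytest

from thermosar import (CameraModel, aggregate_trials,
                       environmental_correction, estimate_sar_eff,
                       generate_preset, initial_slope, quantize,
                       simulate_trials, true_response)
from thermosar.thermography import DEFAULT_TIMES_S, PRESETS


class TestTrueResponse:
    def test_zero_power_is_identically_zero(self):
        assert np.allclose(true_response(0.0, 0.05, 500.0, 0.1,
                                         DEFAULT_TIMES_S), 0.0)

    def test_no_loss_is_exact_line(self):
        t = DEFAULT_TIMES_S
        curve = true_response(0.111, 0.05, 500.0, 0.0, t)
        assert np.allclose(curve, 0.111 * t / 25.0)

    def test_calibrated_curve_near_published_means(self, implant_table):
        p = PRESETS["implant-0.75A"]
        curve = true_response(p["p_abs"], p["mass"], p["heat_capacity"],
                              p["loss_coefficient"], DEFAULT_TIMES_S)
        dev = np.abs(curve - implant_table.implant_mean.to_numpy())
        assert dev.max() < 0.1  # within the display resolution


class TestQuantize:
    @pytest.mark.parametrize("x, expected", [
        (0.04, 0.0), (0.05, 0.1), (0.14, 0.1), (0.15, 0.2),
        (-0.05, -0.1), (-0.04, 0.0),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert quantize(x, 0.1) == pytest.approx(expected)


class TestSimulateTrials:
    def test_noiseless_trials_equal_quantized_truth(self):
        truth = true_response(0.111, 0.05, 500.0, 0.2467, DEFAULT_TIMES_S)
        cam = CameraModel(noise_sd=0.0)
        ts = simulate_trials(truth, DEFAULT_TIMES_S, camera=cam,
                             drift_step_sd=0.0, n_trials=3, seed=1)
        expected = quantize(truth, 0.1) - quantize(truth[0], 0.1)
        assert np.allclose(ts.exposed, expected[None, :])
        assert np.allclose(ts.reference, 0.0)

    def test_baseline_identity(self):
        ts = generate_preset("implant-0.75A", seed=5)
        assert np.all(ts.exposed[:, 0] == 0.0)
        assert np.all(ts.reference[:, 0] == 0.0)
        agg = aggregate_trials(ts)
        assert agg.mean_K.iloc[0] == 0.0

    def test_same_seed_bit_identical(self):
        a = generate_preset("implant-0.75A", seed=11)
        b = generate_preset("implant-0.75A", seed=11)
        assert np.array_equal(a.exposed, b.exposed)
        assert np.array_equal(a.reference, b.reference)
        assert np.array_equal(a.drift_truth, b.drift_truth)
        c = generate_preset("implant-0.75A", seed=12)
        assert not np.array_equal(a.exposed, c.exposed)

    def test_noise_sd_matches_camera_model(self):
        """Monte-Carlo check of the noise model: 1e4 pre-quantization
        samples of a zero truth curve have SD within 5% of the 0.05 K
        sensitivity (the subtracted baseline reading is a shared constant
        and does not widen the spread across times)."""
        times = np.arange(0.0, 1e4, 1.0)
        ts = simulate_trials(np.zeros_like(times), times,
                             camera=CameraModel(), drift_step_sd=0.0,
                             n_trials=1, seed=3)
        assert np.std(ts.exposed_raw[0][1:]) == pytest.approx(0.05, rel=0.05)

    def test_sidecar_and_frame_shapes(self):
        ts = generate_preset("control", seed=2, n_trials=4)
        df = ts.to_frame()
        assert len(df) == 2 * 4 * len(DEFAULT_TIMES_S)
        assert set(df.channel) == {"exposed", "reference"}
        import json
        meta = json.loads(ts.sidecar())
        assert meta["seed"] == 2
        assert meta["truth_params"]["p_abs"] == 0.0


class TestEnvironmentalCorrection:
    def test_reference_equal_exposed_cancels(self):
        x = np.arange(7.0).reshape(1, -1)
        assert np.allclose(environmental_correction(x, x), 0.0)

    def test_mismatched_axes_error(self):
        t1 = np.arange(0, 3601, 600.0)
        t2 = t1 + 60.0
        x = np.zeros((1, len(t1)))
        with pytest.raises(ValueError, match="time axes"):
            environmental_correction(x, x, t1, t2)

    def test_shared_drift_removed_exactly_without_quantization(self):
        truth = true_response(0.111, 0.05, 500.0, 0.2467, DEFAULT_TIMES_S)
        ts = simulate_trials(truth, DEFAULT_TIMES_S,
                             camera=CameraModel(noise_sd=0.0),
                             drift_step_sd=0.05, n_trials=5, seed=9)
        corrected = environmental_correction(ts.exposed_raw,
                                             ts.reference_raw)
        assert np.allclose(corrected, truth[None, :] - truth[0], atol=1e-12)

    def test_corrected_means_within_noise_budget(self):
        """Across seeds, corrected trial means deviate from truth by at
        most one display step plus 3 SE of the 10-trial camera noise."""
        budget = 0.1 + 3 * 0.05 / np.sqrt(10)
        for seed in range(30):
            ts = generate_preset("implant-0.75A", seed=seed)
            agg = aggregate_trials(ts, corrected=True)
            dev = np.abs(agg.mean_K.to_numpy() - ts.truth)
            assert dev.max() <= budget

    def test_correction_reduces_variance_under_dominant_drift(self):
        """When ambient drift dominates camera noise, subtracting the
        reference channel lowers the variance of the trial means.  (Below
        that crossover the correction's doubled camera noise outweighs
        the removed drift; see the methods note.)"""
        corrected_err, uncorrected_err = [], []
        for seed in range(120):
            ts = generate_preset("implant-0.75A", seed=seed,
                                 drift_step_sd=0.1)
            corrected_err.append(ts.corrected().mean(axis=0) - ts.truth)
            uncorrected_err.append(ts.exposed.mean(axis=0) - ts.truth)
        var_c = np.var(np.asarray(corrected_err)[:, 1:])
        var_u = np.var(np.asarray(uncorrected_err)[:, 1:])
        assert var_c <= var_u


class TestAggregate:
    def test_identical_trials_zero_sd(self):
        truth = true_response(0.111, 0.05, 500.0, 0.2467, DEFAULT_TIMES_S)
        ts = simulate_trials(truth, DEFAULT_TIMES_S,
                             camera=CameraModel(noise_sd=0.0),
                             drift_step_sd=0.0, n_trials=5, seed=0)
        agg = aggregate_trials(ts)
        assert np.allclose(agg.sd_K, 0.0)

    def test_two_value_closed_form(self):
        ts = simulate_trials(np.zeros(2), np.array([0.0, 600.0]),
                             camera=CameraModel(noise_sd=0.0),
                             drift_step_sd=0.0, n_trials=2, seed=0)
        ts.exposed[:, 1] = [0.3, 0.5]
        ts.reference[:, 1] = 0.0
        agg = aggregate_trials(ts)
        assert agg.mean_K.iloc[1] == pytest.approx(0.4)
        assert agg.sd_K.iloc[1] == pytest.approx(0.14142, abs=1e-4)

    def test_single_trial_sd_errors(self):
        ts = generate_preset("control", seed=1, n_trials=1)
        with pytest.raises(ValueError):
            aggregate_trials(ts)

    def test_preset_aggregates_track_published_table(self, implant_table):
        """Most aggregated time points fall within one display step of
        the published implant column, across seeds."""
        target = implant_table.implant_mean.to_numpy()
        fracs = []
        for seed in range(20):
            agg = aggregate_trials(generate_preset("implant-0.75A",
                                                   seed=seed))
            fracs.append(np.mean(np.abs(agg.mean_K.to_numpy() - target)
                                 <= 0.1))
        assert np.mean(fracs) >= 0.6


class TestEndToEndRecovery:
    def test_estimator_chain_recovers_generator_truth(self):
        """Generate -> correct -> aggregate -> slope -> SAR_eff recovers
        the slope-referenced truth within the quantization tolerance, and
        exactly once noise and quantization are switched off."""
        p = PRESETS["implant-0.75A"]
        c = p["heat_capacity"]
        truth_curve = true_response(p["p_abs"], p["mass"], c,
                                    p["loss_coefficient"], DEFAULT_TIMES_S)
        truth_sar = c * initial_slope(DEFAULT_TIMES_S, truth_curve).slope
        tol = c * 0.1 / 1200.0  # one display step over the fit window
        recovered = []
        for seed in range(60):
            agg = aggregate_trials(generate_preset("implant-0.75A",
                                                   seed=seed))
            slope = initial_slope(agg.time_min * 60.0, agg.mean_K).slope
            recovered.append(estimate_sar_eff(slope, c).sar_eff)
        assert abs(np.median(recovered) - truth_sar) <= tol
        # noise- and quantization-free measurement is exact
        clean = aggregate_trials(generate_preset(
            "implant-0.75A", seed=0, drift_step_sd=0.0,
            camera=CameraModel(noise_sd=0.0, display_resolution=1e-12)))
        slope = initial_slope(clean.time_min * 60.0, clean.mean_K).slope
        assert estimate_sar_eff(slope, c).sar_eff == pytest.approx(
            truth_sar, rel=1e-9)
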