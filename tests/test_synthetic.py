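"""Generator correctness: VAR sampling, schedules, boluses, waveforms."""

import numpy as np
import pandas as pd
import pytest

import hemodyn as hd
from hemodyn.synthetic import spectral_radius


class TestSimulateVar:
    def test_white_noise_sample_covariance_is_identity(self):
        spec = hd.VarProcessSpec(
            coeffs=np.zeros((1, 2, 2)), noise_cov=np.eye(2), dt=0.5
        )
        x = hd.simulate_var(spec, 50_000, seed=1)
        cov = np.cov(x.T)
        # 3 standard errors: SE(diag) ~ sqrt(2/n), SE(offdiag) ~ 1/sqrt(n)
        assert np.all(np.abs(np.diag(cov) - 1.0) < 3 * np.sqrt(2 / 50_000) * 1.5)
        assert abs(cov[0, 1]) < 3 / np.sqrt(50_000) * 1.5

    def test_ar1_variance_matches_yule_walker(self):
        # stationary variance of x_t = 0.9 x_{t-1} + e_t is 1/(1-0.81)
        spec = hd.VarProcessSpec(
            coeffs=np.array([[[0.9, 0.0], [0.0, 0.0]]]), noise_cov=np.eye(2), dt=0.5
        )
        x = hd.simulate_var(spec, 50_000, seed=2)
        assert x[:, 0].var() == pytest.approx(1.0 / (1.0 - 0.81), abs=0.35)

    def test_unit_root_spec_rejected_with_radius_diagnostic(self):
        with pytest.raises(ValueError, match="spectral radius"):
            hd.VarProcessSpec(
                coeffs=np.array([[[1.1, 0.0], [0.0, 1.1]]]), noise_cov=np.eye(2)
            )

    def test_noise_cov_must_be_symmetric_positive(self):
        with pytest.raises(ValueError, match="symmetric"):
            hd.VarProcessSpec(
                coeffs=np.zeros((1, 2, 2)),
                noise_cov=np.array([[1.0, 0.5], [0.0, 1.0]]),
            )
        with pytest.raises(ValueError, match="positive"):
            hd.VarProcessSpec(
                coeffs=np.zeros((1, 2, 2)),
                noise_cov=np.array([[1.0, 2.0], [2.0, 1.0]]),
            )

    def test_seeded_determinism(self, var_spec):
        a = hd.simulate_var(var_spec, 500, seed=7)
        b = hd.simulate_var(var_spec, 500, seed=7)
        c = hd.simulate_var(var_spec, 500, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_sample_count_floor(self, var_spec):
        with pytest.raises(ValueError, match="10\\*p"):
            hd.simulate_var(var_spec, 5, seed=0)

    def test_piecewise_carries_state_and_matches_single_run(self, var_spec):
        # a single-spec piecewise run equals the monolithic run
        a = hd.simulate_var_piecewise([(var_spec, 300), (var_spec, 200)], seed=5)
        b = hd.simulate_var(var_spec, 500, seed=5)
        np.testing.assert_allclose(a, b)

    def test_scaled_coupling_targets_only_the_cross_term(self, var_spec):
        boosted = var_spec.scaled_coupling(2.0)
        assert np.allclose(
            boosted.coeffs[:, hd.PRESSURE, hd.FLOW],
            2.0 * var_spec.coeffs[:, hd.PRESSURE, hd.FLOW],
        )
        mask = np.ones_like(var_spec.coeffs, dtype=bool)
        mask[:, hd.PRESSURE, hd.FLOW] = False
        np.testing.assert_array_equal(boosted.coeffs[mask], var_spec.coeffs[mask])
        assert spectral_radius(boosted.coeffs) < 1.0


class TestPhaseSchedule:
    def test_multipliers_satisfy_pressure_identity_everywhere(self):
        schedule = hd.lps_schedule()
        t = np.linspace(0.0, schedule.span[1], 5001)  # includes ramps
        map_m, sbf_m, svr_m = schedule.multipliers(t)
        np.testing.assert_allclose(map_m, sbf_m * svr_m, rtol=1e-12)

    def test_inconsistent_map_multiplier_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hd.PhaseEpoch(0.0, 10.0, sbf_mult=0.8, svr_mult=1.0, ramp=0.0, map_mult=1.0)

    def test_non_contiguous_epochs_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            hd.PhaseSchedule(
                (hd.PhaseEpoch(0.0, 10.0, ramp=0.0), hd.PhaseEpoch(20.0, 30.0, ramp=0.0))
            )

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hd.PhaseEpoch(0.0, 10.0, sbf_mult=-0.5, svr_mult=1.0, ramp=0.0)


class TestSimulateBeats:
    def test_conservation_identities_to_machine_precision(self, lps_beat_table):
        table, _ = lps_beat_table
        sv_hr = table["sv"] * table["hr"]
        svr_sbf = table["svr"] * table["sbf_mean"]
        assert np.max(np.abs(sv_hr - table["sbf_mean"]) / table["sbf_mean"]) < 1e-12
        assert np.max(np.abs(svr_sbf - table["ap_mean"]) / table["ap_mean"]) < 1e-12

    def test_pressure_bracketing(self, lps_beat_table):
        table, _ = lps_beat_table
        assert (table["diastolic"] <= table["ap_mean"]).all()
        assert (table["ap_mean"] <= table["systolic"]).all()

    def test_deterministic_given_seed(self):
        cfg = hd.SimulationConfig(seed=42, duration=30.0)
        pd.testing.assert_frame_equal(hd.simulate_beats(cfg), hd.simulate_beats(cfg))

    def test_constant_schedule_beat_count_and_level(self, clean_config):
        table = hd.simulate_beats(clean_config)
        assert abs(len(table) - 360) <= 1
        np.testing.assert_allclose(table["ap_mean"], clean_config.map0, rtol=1e-12)

    def test_implied_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError, match="non-positive|diastolic"):
            hd.simulate_beats(
                hd.SimulationConfig(
                    seed=0, duration=30.0, map0=5.0, pulse_pressure=40.0, var_spec=None
                )
            )


class TestInjectBolus:
    def test_neutral_peak_multiplier_leaves_series_unchanged(self, clean_config):
        table = hd.simulate_beats(clean_config)
        event = hd.BolusEventSpec(time=20.0, peak_mult=1.0, time_to_peak=5.0, k=0.1)
        out = hd.inject_bolus(table, event)
        np.testing.assert_allclose(out["svr"], table["svr"])
        np.testing.assert_allclose(out["ap_mean"], table["ap_mean"])

    def test_identity_preserved_after_bolus(self, bolus_table):
        table, _, _ = bolus_table
        svr_sbf = table["svr"] * table["sbf_mean"]
        assert np.max(np.abs(svr_sbf - table["ap_mean"]) / table["ap_mean"]) < 1e-12

    def test_event_outside_span_rejected(self, clean_config):
        table = hd.simulate_beats(clean_config)
        event = hd.BolusEventSpec(time=500.0, peak_mult=1.5)
        with pytest.raises(ValueError, match="outside"):
            hd.inject_bolus(table, event)

    def test_overlapping_events_rejected(self, clean_config):
        table = hd.simulate_beats(clean_config)
        first = hd.BolusEventSpec(time=10.0, peak_mult=1.5, time_to_peak=5.0, k=0.2)
        second = hd.BolusEventSpec(time=20.0, peak_mult=1.5, time_to_peak=5.0, k=0.2)
        out = hd.inject_bolus(table, first)
        with pytest.raises(ValueError, match="overlap"):
            hd.inject_bolus(out, second)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            hd.BolusEventSpec(time=0.0, peak_mult=1.5, k=-0.1)
        with pytest.raises(ValueError):
            hd.BolusEventSpec(time=0.0, peak_mult=1.5, time_to_peak=0.0)


class TestSimulateWaveforms:
    def test_bit_identical_records_for_same_seed(self):
        cfg = hd.SimulationConfig(seed=3, duration=10.0)
        rec_a, truth_a = hd.simulate_waveforms(cfg)
        rec_b, truth_b = hd.simulate_waveforms(cfg)
        np.testing.assert_array_equal(rec_a.pressure, rec_b.pressure)
        np.testing.assert_array_equal(rec_a.flow, rec_b.flow)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_waveform_beat_means_match_truth(self, clean_recording):
        record, truth = clean_recording
        # per-beat sample averages vs the analytic ground truth
        T = truth["duration"].iloc[0]
        idx = np.searchsorted(record.times, truth["t_onset"].to_numpy())
        means = np.add.reduceat(record.pressure, idx)[:-1] / np.diff(idx)
        np.testing.assert_allclose(
            means, truth["ap_mean"].to_numpy()[:-1], rtol=5e-3
        )
        assert T == pytest.approx(60.0 / 360.0)
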