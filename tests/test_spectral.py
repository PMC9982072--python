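"""Coherence, VAR fitting and PDC: closed forms, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hemodyn as hd
from hemodyn.waveform import EvenSeries


def _series(flow, pressure, dt=0.5):
    return EvenSeries(dt=dt, flow=np.asarray(flow), pressure=np.asarray(pressure))


def brute_force_pdc(coeffs, dt, freqs):
    """Independent evaluation of squared PDC straight from its definition."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, m, _ = coeffs.shape
    out = np.empty((m, m, len(freqs)))
    for fi, f in enumerate(freqs):
        abar = np.eye(m, dtype=complex)
        for k in range(1, p + 1):
            abar = abar - coeffs[k - 1] * np.exp(-2j * np.pi * f * k * dt)
        for j in range(m):
            col = np.abs(abar[:, j]) ** 2
            out[:, j, fi] = col / col.sum()
    return out


def random_stable_spec(rng, p):
    """Random VAR(p) rescaled lag-wise until comfortably stationary."""
    coeffs = rng.normal(scale=0.4, size=(p, 2, 2))
    rho = hd.synthetic.spectral_radius(coeffs)
    if rho >= 0.9:
        scale = 0.8 / rho
        coeffs = coeffs * (scale ** np.arange(1, p + 1))[:, None, None]
    return hd.VarProcessSpec(coeffs=coeffs, noise_cov=np.eye(2), dt=0.5)


class TestWelchCoherence:
    def test_duplicated_channel_gives_unit_coherence(self):
        x = np.random.default_rng(0).standard_normal(4096)
        coh = hd.welch_coherence(_series(x, x))
        assert np.all(coh.coherence > 0.999999)

    def test_equal_variance_noise_gives_half(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_000)
        n = rng.standard_normal(20_000)
        coh = hd.welch_coherence(_series(x, x + n))
        # SNR/(1+SNR) = 0.5 at equal variance
        assert coh.band_mean("coherence", band=(0.0, 1.0)) == pytest.approx(0.5, abs=0.05)

    def test_independent_channels_low_band_mean(self):
        rng = np.random.default_rng(2)
        coh = hd.welch_coherence(
            _series(rng.standard_normal(20_000), rng.standard_normal(20_000))
        )
        assert coh.band_mean("coherence", band=(0.0, 1.0)) < 0.1

    def test_single_segment_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="2 Welch segments"):
            hd.welch_coherence(
                _series(rng.standard_normal(200), rng.standard_normal(200))
            )

    def test_channel_exchange_symmetry(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(5_000)
        y = 0.6 * x + rng.standard_normal(5_000)
        a = hd.welch_coherence(_series(x, y)).coherence
        b = hd.welch_coherence(_series(y, x)).coherence
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        coh = hd.welch_coherence(
            _series(rng.standard_normal(4_000), rng.standard_normal(4_000))
        )
        assert np.all(coh.coherence >= 0.0) and np.all(coh.coherence <= 1.0)


class TestFitVar:
    def test_recovers_known_var2(self, var_spec):
        x = hd.simulate_var(var_spec, 10_000, seed=9)
        model = hd.fit_var(_series(x[:, 0], x[:, 1]), max_order=20)
        assert model.order == 2
        assert np.max(np.abs(model.coeffs - var_spec.coeffs)) < 0.05
        assert model.stable

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((5_000, 2))
        model = hd.fit_var(_series(x[:, 0], x[:, 1]), order=1)
        assert np.max(np.abs(model.coeffs)) < 0.05

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((100, 2))
        with pytest.raises(ValueError, match="at least"):
            hd.fit_var(_series(x[:, 0], x[:, 1]), max_order=20)

    def test_order_selection_boundary_flagged(self, var_spec):
        x = hd.simulate_var(var_spec, 5_000, seed=12)
        model = hd.fit_var(_series(x[:, 0], x[:, 1]), max_order=1)
        assert model.order == 1 and model.order_at_boundary


class TestPdc:
    def test_unidirectional_model_structural_zero(self):
        spec = hd.VarProcessSpec(
            coeffs=np.array([[[0.5, 0.0], [0.4, 0.5]]]), noise_cov=np.eye(2), dt=0.5
        )
        spectra = hd.pdc(spec, np.linspace(0.0, 1.0, 101))
        # channel 1 drives channel 2; the reverse direction is exactly zero
        assert np.all(spectra.pdc[0, 1] == 0.0)
        assert np.all(spectra.pdc[1, 0] > 0.0)
        col_sums = spectra.pdc.sum(axis=0)
        assert np.max(np.abs(col_sums - 1.0)) < 1e-10

    def test_diagonal_model_has_no_cross_terms(self):
        spec = hd.VarProcessSpec(
            coeffs=np.array([[[0.5, 0.0], [0.0, 0.3]]]), noise_cov=np.eye(2), dt=0.5
        )
        spectra = hd.pdc(spec)
        assert np.all(spectra.pdc[0, 1] == 0.0)
        assert np.all(spectra.pdc[1, 0] == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        spec = random_stable_spec(rng, p=3)
        freqs = np.linspace(0.0, 1.0, 101)
        expected = brute_force_pdc(spec.coeffs, spec.dt, freqs)
        np.testing.assert_allclose(hd.pdc(spec, freqs).pdc, expected, atol=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), p=st.integers(1, 4))
    def test_column_normalization_is_exact(self, seed, p):
        spec = random_stable_spec(np.random.default_rng(seed), p)
        spectra = hd.pdc(spec)
        col_sums = spectra.pdc.sum(axis=0)
        np.testing.assert_allclose(col_sums, 1.0, atol=1e-12)
        assert np.all(spectra.pdc >= 0.0) and np.all(spectra.pdc <= 1.0)

    def test_directionality_not_symmetric(self, var_spec):
        spectra = hd.pdc(var_spec)
        fp = spectra.band_mean("pdc", source="flow", target="pressure")
        pf = spectra.band_mean("pdc", source="pressure", target="flow")
        assert fp > 10 * pf  # flow drives pressure in the default model

    def test_frequency_above_nyquist_rejected(self, var_spec):
        with pytest.raises(ValueError, match="Nyquist|Hz"):
            hd.pdc(var_spec, np.array([1.5]))

    def test_estimated_pdc_tracks_analytic_within_band(self, var_spec):
        x = hd.simulate_var(var_spec, 10_000, seed=14)
        model = hd.fit_var(_series(x[:, 0], x[:, 1]), max_order=20)
        freqs = np.linspace(0.0, 1.0, 201)
        est = hd.pdc(model, freqs)
        true = hd.pdc(var_spec, freqs)
        mask = (freqs > 0.0) & (freqs <= 0.2)
        dev = np.abs(est.pdc[..., mask] - true.pdc[..., mask])
        assert dev.mean() < 0.05


class TestVarSpectrumFactorization:
    def test_fitted_spectrum_matches_welch_estimate(self, var_spec):
        x = hd.simulate_var(var_spec, 40_000, seed=15)
        series = _series(x[:, 0], x[:, 1])
        coh = hd.welch_coherence(series, segment_length=512)
        from scipy.signal import welch

        freqs, psd_flow = welch(series.flow, fs=2.0, nperseg=512, noverlap=256)
        analytic = hd.var_spectrum(var_spec, freqs)
        band = (freqs > 0.02) & (freqs < 0.9)
        ratio = psd_flow[band] / np.real(analytic[band, 0, 0])
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)


class TestBandSummary:
    def test_identical_subjects_give_zero_width_interval(self):
        summ = hd.band_summary([0.4] * 6, n_boot=500, seed=1)
        assert summ.median == 0.4
        assert summ.ci_low == summ.ci_high == 0.4

    def test_same_seed_reproduces_interval(self):
        values = [0.2, 0.4, 0.5, 0.35, 0.6, 0.45, 0.3]
        a = hd.band_summary(values, n_boot=1000, seed=3)
        b = hd.band_summary(values, n_boot=1000, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_small_bootstrap_count_warns(self):
        with pytest.warns(UserWarning, match="bootstrap"):
            hd.band_summary([0.1, 0.2, 0.3], n_boot=50, seed=0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            hd.band_summary([0.5], n_boot=500)

    def test_interval_covers_population_median_at_nominal_rate(self):
        # subjects ~ N(0.6, 0.05), n = 9: percentile-bootstrap CI for the
        # median should cover 0.6 in roughly 95% of replications
        rng = np.random.default_rng(16)
        covered = 0
        reps = 300
        for _ in range(reps):
            values = rng.normal(0.6, 0.05, size=9)
            summ = hd.band_summary(
                values, n_boot=500, seed=int(rng.integers(2**31 - 1))
            )
            covered += summ.ci_low <= 0.6 <= summ.ci_high
        assert 0.85 <= covered / reps <= 0.995


@pytest.fixture(scope="module")
def stationary_tables():
    tables = []
    for seed in range(4):
        cfg = hd.SimulationConfig(seed=100 + seed, duration=1300.0)
        tables.append(hd.simulate_beats(cfg))
    return tables


class TestWindowedCoupling:
    def test_stationary_windows_statistically_indistinguishable(
        self, stationary_tables
    ):
        res = hd.windowed_coupling(
            stationary_tables,
            window_centers=[300.0, 900.0],
            window_length=500.0,
            config=hd.CouplingConfig(seed=0, n_boot=500),
        )
        s = res["summary"].set_index(["window_center", "quantity"])
        for q in ("coherence", "pdc_flow_to_pressure"):
            early = s.loc[(300.0, q)]
            late = s.loc[(900.0, q)]
            assert early["ci_low"] <= late["median"] <= early["ci_high"] or abs(
                late["median"] - early["median"]
            ) < 0.1

    def test_gain_doubling_raises_flow_to_pressure_band(self):
        kids = np.random.SeedSequence(17).spawn(6)
        tables = []
        for child in kids:
            cfg = hd.SimulationConfig(
                seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                duration=4900.0,
                coupling_boost=(2400.0, 4800.0, 2.0),
            )
            tables.append(hd.simulate_beats(cfg))
        res = hd.windowed_coupling(
            tables,
            window_centers=[300.0, 3600.0],
            window_length=600.0,
            config=hd.CouplingConfig(seed=17, n_boot=1000),
        )
        s = res["summary"].set_index(["window_center", "quantity"])
        q = "pdc_flow_to_pressure"
        assert s.loc[(3600.0, q), "median"] > s.loc[(300.0, q), "ci_high"]

    def test_window_beyond_recording_rejected(self, stationary_tables):
        with pytest.raises(ValueError, match="beyond"):
            hd.windowed_coupling(
                stationary_tables[0],
                window_centers=[1290.0],
                window_length=600.0,
            )
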