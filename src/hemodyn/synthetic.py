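"""Synthetic pulsatile hemodynamics with known ground truth.

Emulates two-channel recordings of arterial pressure (mmHg) and ascending
aortic flow (mL/min) from an unanesthetized rat: fast pulsatile waveforms at a
typical rat heart rate (300-450 bpm), slow (<0.2 Hz) beat-to-beat fluctuations
with controllable directed flow<->pressure coupling produced by a stable
bivariate vector-autoregressive (VAR) process, a three-phase endotoxin-like
schedule of mean pressure / flow / resistance trends, and transient bolus
vasoconstrictor responses with exponential recovery.

Every generator is seeded and deterministic, and the per-beat identity
``MAP = SVR x SBF`` holds exactly in the ground-truth tables it emits, so each
downstream analysis stage can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .waveform import WaveformRecord

__all__ = [
    "FLOW",
    "PRESSURE",
    "CHANNELS",
    "VarProcessSpec",
    "PhaseEpoch",
    "PhaseSchedule",
    "BolusEventSpec",
    "SimulationConfig",
    "companion_matrix",
    "spectral_radius",
    "default_var_spec",
    "baseline_schedule",
    "lps_schedule",
    "simulate_var",
    "simulate_var_piecewise",
    "simulate_beats",
    "simulate_waveforms",
    "inject_bolus",
]

# channel ordering used throughout the package
FLOW = 0
PRESSURE = 1
CHANNELS = ("flow", "pressure")


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of a VAR(p) coefficient stack of shape ``(p, m, m)``."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, m, _ = coeffs.shape
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.hstack(list(coeffs))
    if p > 1:
        comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stationary iff < 1)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


@dataclass(frozen=True)
class VarProcessSpec:
    """A stable VAR(p) process: lag matrices, innovation covariance, clock.

    Parameters
    ----------
    coeffs
        Array of shape ``(p, m, m)``; ``coeffs[k-1]`` is the lag-k matrix A_k
        in ``x_t = sum_k A_k x_{t-k} + e_t``.  Element ``[i, j]`` maps channel
        j to channel i (so ``coeffs[:, PRESSURE, FLOW]`` is the flow->pressure
        pathway).
    noise_cov
        Innovation covariance (symmetric positive definite, ``(m, m)``).
    dt
        Sampling interval of the slow series in seconds (default 0.5 s, i.e.
        the 2 Hz slow-fluctuation clock).
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    dt: float = 0.5

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim == 2:
            coeffs = coeffs[None, :, :]
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, m, m)")
        cov = np.asarray(self.noise_cov, dtype=float)
        if cov.shape != (coeffs.shape[1], coeffs.shape[1]):
            raise ValueError("noise_cov shape must match the channel count")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ValueError("noise_cov must have positive eigenvalues")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        rho = spectral_radius(coeffs)
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR process: companion spectral radius {rho:.4f} >= 1"
            )
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", cov)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def nchan(self) -> int:
        return self.coeffs.shape[1]

    def scaled_coupling(
        self, factor: float, source: int = FLOW, target: int = PRESSURE
    ) -> "VarProcessSpec":
        """Copy of the spec with the source->target cross-lags scaled."""
        coeffs = self.coeffs.copy()
        coeffs[:, target, source] *= factor
        return VarProcessSpec(coeffs=coeffs, noise_cov=self.noise_cov, dt=self.dt)


def default_var_spec(dt: float = 0.5) -> VarProcessSpec:
    """Slow-fluctuation VAR(2) used as the study condition.

    Flow drives pressure (the autoregulation signature: the regulated variable
    leads adjustments of the other) with a weak passive pressure->flow return
    path.  Innovation SDs of ~2% keep fractional beat-to-beat fluctuations at
    the few-percent level typical of resting recordings.
    """
    a1 = np.array([[0.30, 0.05], [0.35, 0.25]])
    a2 = np.array([[0.12, 0.00], [0.08, 0.05]])
    cov = np.array([[4.0e-4, 0.5e-4], [0.5e-4, 2.5e-4]])
    return VarProcessSpec(coeffs=np.stack([a1, a2]), noise_cov=cov, dt=dt)


def simulate_var(
    spec: VarProcessSpec,
    n: int,
    seed: int | None = None,
    burn_in: int | None = None,
) -> np.ndarray:
    """Draw ``n`` samples of the stationary VAR process (burn-in discarded).

    Same seed -> identical output.  Raises if ``n`` is too small relative to
    the order (``n >= 10 p``).
    """
    return simulate_var_piecewise([(spec, int(n))], seed=seed, burn_in=burn_in)


def simulate_var_piecewise(
    segments: Sequence[tuple[VarProcessSpec, int]],
    seed: int | None = None,
    burn_in: int | None = None,
) -> np.ndarray:
    """Concatenate VAR segments, carrying the process state across joins.

    Each element of ``segments`` is ``(spec, n_samples)``; all specs must share
    the channel count.  The burn-in uses the first segment's spec.
    """
    if not segments:
        raise ValueError("need at least one segment")
    m = segments[0][0].nchan
    max_p = max(spec.order for spec, _ in segments)
    for spec, n in segments:
        if spec.nchan != m:
            raise ValueError("all segments must share the channel count")
        if n < 10 * spec.order:
            raise ValueError(
                f"need at least 10*p = {10 * spec.order} samples per segment, got {n}"
            )
    burn = int(burn_in) if burn_in is not None else max(200, 20 * max_p)
    total = burn + sum(n for _, n in segments)
    rng = np.random.default_rng(seed)
    x = np.zeros((total, m))
    plan = [(segments[0][0], burn)] + [(s, int(n)) for s, n in segments]
    pos = 0
    for spec, n in plan:
        if n == 0:
            continue
        chol = np.linalg.cholesky(spec.noise_cov)
        eps = rng.standard_normal((n, m)) @ chol.T
        coeffs = spec.coeffs
        p = spec.order
        for t in range(pos, pos + n):
            acc = eps[t - pos].copy()
            for k in range(p):
                if t - k - 1 >= 0:
                    acc += coeffs[k] @ x[t - k - 1]
            x[t] = acc
        pos += n
    return x[burn:]


@dataclass(frozen=True)
class PhaseEpoch:
    """One epoch of the slow hemodynamic schedule.

    Flow (SBF) and resistance (SVR) multipliers are the free parameters; the
    pressure multiplier is their product so that ``MAP = SVR x SBF`` holds at
    every instant, including during ramps.  ``ramp`` is the linear transition
    (seconds) from the previous epoch's multipliers at the epoch start.
    """

    start: float
    end: float
    sbf_mult: float = 1.0
    svr_mult: float = 1.0
    ramp: float = 120.0
    map_mult: float | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("epoch end must exceed start")
        if self.sbf_mult <= 0 or self.svr_mult <= 0:
            raise ValueError("multipliers must be positive")
        if self.ramp < 0 or self.ramp > (self.end - self.start):
            raise ValueError("ramp must lie within the epoch")
        derived = self.sbf_mult * self.svr_mult
        if self.map_mult is None:
            object.__setattr__(self, "map_mult", derived)
        elif abs(self.map_mult - derived) > 1e-8:
            raise ValueError(
                f"inconsistent multipliers: MAP {self.map_mult} != "
                f"SVR x SBF = {derived}"
            )


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous, non-overlapping epochs of multiplicative slow trends."""

    epochs: tuple[PhaseEpoch, ...]

    def __post_init__(self) -> None:
        epochs = tuple(self.epochs)
        if not epochs:
            raise ValueError("schedule needs at least one epoch")
        for a, b in zip(epochs[:-1], epochs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError("epochs must be contiguous and ordered")
        object.__setattr__(self, "epochs", epochs)

    @property
    def span(self) -> tuple[float, float]:
        return (self.epochs[0].start, self.epochs[-1].end)

    def multipliers(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(map, sbf, svr) multipliers at times ``t``.

        SBF and SVR ramp linearly between epoch targets; the pressure
        multiplier is their product (exact per-instant identity).
        """
        t = np.asarray(t, dtype=float)
        knots_t: list[float] = []
        knots_sbf: list[float] = []
        knots_svr: list[float] = []
        prev_sbf = self.epochs[0].sbf_mult
        prev_svr = self.epochs[0].svr_mult
        for i, ep in enumerate(self.epochs):
            if i == 0:
                knots_t.append(ep.start)
                knots_sbf.append(ep.sbf_mult)
                knots_svr.append(ep.svr_mult)
            else:
                knots_t.extend([ep.start, ep.start + max(ep.ramp, 1e-12)])
                knots_sbf.extend([prev_sbf, ep.sbf_mult])
                knots_svr.extend([prev_svr, ep.svr_mult])
            prev_sbf, prev_svr = ep.sbf_mult, ep.svr_mult
        knots_t.append(self.epochs[-1].end)
        knots_sbf.append(prev_sbf)
        knots_svr.append(prev_svr)
        sbf = np.interp(t, knots_t, knots_sbf)
        svr = np.interp(t, knots_t, knots_svr)
        return sbf * svr, sbf, svr


def baseline_schedule(duration: float) -> PhaseSchedule:
    """Single steady-state epoch covering ``[0, duration]``."""
    return PhaseSchedule((PhaseEpoch(0.0, float(duration), 1.0, 1.0, ramp=0.0),))


def lps_schedule(
    onset: float = 600.0, scale: float = 1.0, ramp: float = 120.0
) -> PhaseSchedule:
    """Endotoxin-like three-phase schedule after a baseline period.

    Phase 1 (20 min): flow falls ~22%, resistance rises so pressure holds.
    Phase 2 (40 min): resistance collapses to 0.6x with flow back at baseline,
    i.e. the ~40% hypotension with stabilized flow.
    Phase 3 (50 min): pressure recovers via a resistance overshoot while flow
    falls again.  ``scale`` shrinks the phase durations for short recordings.
    """
    t0 = float(onset)
    d1, d2, d3 = 1200.0 * scale, 2400.0 * scale, 3000.0 * scale
    return PhaseSchedule(
        (
            PhaseEpoch(0.0, t0, 1.0, 1.0, ramp=0.0),
            PhaseEpoch(t0, t0 + d1, sbf_mult=0.78, svr_mult=1.0 / 0.78, ramp=ramp),
            PhaseEpoch(t0 + d1, t0 + d1 + d2, sbf_mult=1.0, svr_mult=0.60, ramp=ramp),
            PhaseEpoch(
                t0 + d1 + d2, t0 + d1 + d2 + d3, sbf_mult=0.80, svr_mult=1.25, ramp=ramp
            ),
        )
    )


@dataclass(frozen=True)
class BolusEventSpec:
    """Transient vasoconstrictor bolus acting multiplicatively on SVR.

    The resistance multiplier rises linearly to ``peak_mult`` over
    ``time_to_peak`` seconds, then relaxes exponentially with rate ``k``
    toward a plateau that retains ``plateau_frac`` of the peak rise
    (incomplete escape).
    """

    time: float
    peak_mult: float
    time_to_peak: float = 10.0
    k: float = 0.08
    plateau_frac: float = 0.15
    dose: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("recovery rate constant k must be positive")
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be positive")
        if self.peak_mult <= 0:
            raise ValueError("peak multiplier must be positive")
        if not 0.0 <= self.plateau_frac <= 1.0:
            raise ValueError("plateau_frac must lie in [0, 1]")

    @property
    def duration(self) -> float:
        """Effective response duration (rise plus ~6 decay time constants)."""
        return self.time_to_peak + 6.0 / self.k

    def multiplier(self, t: np.ndarray) -> np.ndarray:
        """SVR multiplier at absolute times ``t``."""
        tau = np.asarray(t, dtype=float) - self.time
        rise = self.peak_mult - 1.0
        up = 1.0 + rise * np.clip(tau / self.time_to_peak, 0.0, 1.0)
        decay = 1.0 + rise * (
            self.plateau_frac
            + (1.0 - self.plateau_frac)
            * np.exp(-self.k * np.maximum(tau - self.time_to_peak, 0.0))
        )
        return np.where(tau < 0.0, 1.0, np.where(tau <= self.time_to_peak, up, decay))


def _default_spec() -> VarProcessSpec:
    return default_var_spec()


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic recording.

    Baselines follow the resting rat: MAP 92 mmHg, aortic flow 110 mL/min
    (SVR ~0.84 mmHg.min/mL), heart rate 360 bpm, pulse pressure 40 mmHg,
    500 Hz acquisition.  ``coupling_boost = (start, end, factor)`` scales the
    flow->pressure VAR cross-lags inside a time span (used to emulate the
    strengthening of autoregulatory coupling).
    """

    seed: int = 0
    fs: float = 500.0
    duration: float = 120.0
    hr: float = 360.0
    map0: float = 92.0
    sbf0: float = 110.0
    pulse_pressure: float = 40.0
    var_spec: VarProcessSpec | None = field(default_factory=_default_spec)
    schedule: PhaseSchedule | None = None
    boluses: tuple[BolusEventSpec, ...] = ()
    coupling_boost: tuple[float, float, float] | None = None
    noise_sd_pressure: float = 1.0
    noise_sd_flow: float = 2.0
    systole_frac: float = 0.35
    rise_frac: float = 0.12

    def __post_init__(self) -> None:
        for name in ("fs", "duration", "hr", "map0", "sbf0", "pulse_pressure"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_pressure < 0 or self.noise_sd_flow < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.rise_frac < self.systole_frac < 1:
            raise ValueError("need 0 < rise_frac < systole_frac < 1")
        svr0 = self.map0 / self.sbf0
        if not np.isfinite(svr0) or svr0 <= 0:
            raise ValueError("baseline SVR = MAP/SBF must be finite and positive")
        object.__setattr__(self, "boluses", tuple(self.boluses))

    @property
    def svr0(self) -> float:
        return self.map0 / self.sbf0


def _slow_fluctuations(config: SimulationConfig, times: np.ndarray, seed) -> np.ndarray:
    """Fractional (dimensionless) slow fluctuations sampled at ``times``."""
    if config.var_spec is None:
        return np.zeros((len(times), 2))
    spec = config.var_spec
    dt = spec.dt
    n_slow = int(np.ceil(config.duration / dt)) + 2
    if config.coupling_boost is None:
        x = _piecewise_relaxed([(spec, n_slow)], seed)
    else:
        b0, b1, factor = config.coupling_boost
        i0 = int(np.clip(round(b0 / dt), 0, n_slow))
        i1 = int(np.clip(round(b1 / dt), i0, n_slow))
        boosted = spec.scaled_coupling(factor)
        # short flanking segments are legal here: the state carries over
        segs = [(s, n) for s, n in
                [(spec, i0), (boosted, i1 - i0), (spec, n_slow - i1)] if n > 0]
        x = _piecewise_relaxed(segs, seed)
        x = x[:n_slow]
    slow_t = np.arange(n_slow) * dt
    out = np.column_stack(
        [np.interp(times, slow_t, x[:, FLOW]), np.interp(times, slow_t, x[:, PRESSURE])]
    )
    return out


def _piecewise_relaxed(segments, seed) -> np.ndarray:
    """Piecewise VAR simulation without the per-segment length floor."""
    m = segments[0][0].nchan
    max_p = max(spec.order for spec, _ in segments)
    burn = max(200, 20 * max_p)
    total = burn + sum(n for _, n in segments)
    rng = np.random.default_rng(seed)
    x = np.zeros((total, m))
    plan = [(segments[0][0], burn)] + [(s, int(n)) for s, n in segments]
    pos = 0
    for spec, n in plan:
        if n == 0:
            continue
        chol = np.linalg.cholesky(spec.noise_cov)
        eps = rng.standard_normal((n, m)) @ chol.T
        coeffs = spec.coeffs
        p = spec.order
        for t in range(pos, pos + n):
            acc = eps[t - pos].copy()
            for k in range(p):
                if t - k - 1 >= 0:
                    acc += coeffs[k] @ x[t - k - 1]
            x[t] = acc
        pos += n
    return x[burn:]


def _shape_mean(T: float, rise_frac: float) -> float:
    """Analytic time-average of the unit pressure pulse shape over one beat."""
    t_rise = rise_frac * T
    tau_d = (T - t_rise) / 5.0
    area = (2.0 / np.pi) * t_rise + tau_d * (1.0 - np.exp(-(T - t_rise) / tau_d))
    return area / T


def _check_boluses(boluses: Sequence[BolusEventSpec], t_min: float, t_max: float):
    events = sorted(boluses, key=lambda e: e.time)
    for ev in events:
        if ev.time < t_min or ev.time + ev.time_to_peak > t_max:
            raise ValueError(
                f"bolus at t={ev.time} s falls outside the series span "
                f"[{t_min}, {t_max}] s"
            )
    for a, b in zip(events[:-1], events[1:]):
        if a.time + a.duration > b.time:
            raise ValueError(
                f"overlapping boluses at t={a.time} s and t={b.time} s"
            )
    return events


def simulate_beats(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth per-beat table implied by a configuration.

    Columns: ``t_onset, duration, hr, ap_mean, systolic, diastolic, dpdt_max,
    sbf_mean, sv, svr``.  The conservation identities ``sv*hr == sbf_mean``
    and ``svr*sbf_mean == ap_mean`` hold to machine precision; no measurement
    noise is applied at this level.
    """
    T = 60.0 / config.hr
    n_beats = int(np.ceil(config.duration / T))
    onsets = np.arange(n_beats) * T
    schedule = config.schedule or baseline_schedule(config.duration)
    map_m, sbf_m, _ = schedule.multipliers(onsets)
    ss = np.random.SeedSequence(config.seed)
    var_seed, _p_seed, _f_seed = ss.spawn(3)
    fluct = _slow_fluctuations(config, onsets, var_seed)
    ap = config.map0 * map_m * (1.0 + fluct[:, PRESSURE])
    sbf = config.sbf0 * sbf_m * (1.0 + fluct[:, FLOW])
    if np.any(ap <= 0) or np.any(sbf <= 0):
        raise ValueError(
            "schedule multipliers and fluctuations imply non-positive "
            "pressure or flow"
        )
    svr = ap / sbf
    pp = config.pulse_pressure * (ap / config.map0)
    sbar = _shape_mean(T, config.rise_frac)
    dia = ap - pp * sbar
    if np.any(dia <= 0):
        raise ValueError("implied diastolic pressure is non-positive")
    table = pd.DataFrame(
        {
            "t_onset": onsets,
            "duration": np.full(n_beats, T),
            "hr": np.full(n_beats, config.hr),
            "ap_mean": ap,
            "systolic": dia + pp,
            "diastolic": dia,
            "dpdt_max": pp * np.pi / (2.0 * config.rise_frac * T),
            "sbf_mean": sbf,
            "sv": sbf / config.hr,
            "svr": svr,
        }
    )
    table.attrs["boluses"] = []
    if config.boluses:
        _check_boluses(config.boluses, onsets[0], onsets[-1])
        for ev in sorted(config.boluses, key=lambda e: e.time):
            table = inject_bolus(table, ev)
    return table


def inject_bolus(table: pd.DataFrame, event: BolusEventSpec) -> pd.DataFrame:
    """Overlay a vasoconstrictor bolus on a per-beat table.

    SVR is multiplied by the rise-then-exponential-decay profile; mean
    pressure follows the square root of that multiplier (the response splits
    between a pressure rise and a flow fall) and flow is recomputed so the
    per-beat identity ``MAP = SVR x SBF`` is preserved exactly.
    """
    t = table["t_onset"].to_numpy()
    prior = [e for e in table.attrs.get("boluses", [])]
    _check_boluses(prior + [event], t[0], t[-1])
    prof = event.multiplier(t)
    amp = np.sqrt(prof)
    out = table.copy()
    out["svr"] = table["svr"] * prof
    out["ap_mean"] = table["ap_mean"] * amp
    out["systolic"] = table["systolic"] * amp
    out["diastolic"] = table["diastolic"] * amp
    out["dpdt_max"] = table["dpdt_max"] * amp
    out["sbf_mean"] = out["ap_mean"] / out["svr"]
    out["sv"] = out["sbf_mean"] / out["hr"]
    out.attrs["boluses"] = prior + [event]
    return out


def simulate_waveforms(config: SimulationConfig) -> tuple[WaveformRecord, pd.DataFrame]:
    """Pulsatile 500 Hz waveforms plus the ground-truth per-beat table.

    Each beat is a fast half-sine systolic upstroke followed by an exponential
    diastolic decay (pressure) and a systolic ejection lobe with near-zero
    diastolic flow (flow).  Per-beat waveform means match the ground-truth
    table by construction; additive Gaussian measurement noise is applied to
    the waveforms only.
    """
    table = simulate_beats(config)
    fs = config.fs
    T = 60.0 / config.hr
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    ib = np.minimum((t / T).astype(int), len(table) - 1)
    tau = t - table["t_onset"].to_numpy()[ib]
    t_rise = config.rise_frac * T
    t_sys = config.systole_frac * T
    tau_d = (T - t_rise) / 5.0
    shape = np.where(
        tau <= t_rise,
        np.sin(0.5 * np.pi * tau / t_rise),
        np.exp(-(tau - t_rise) / tau_d),
    )
    dia = table["diastolic"].to_numpy()[ib]
    pp = (table["systolic"] - table["diastolic"]).to_numpy()[ib]
    pressure = dia + pp * shape
    lobe = np.where(tau <= t_sys, np.sin(np.pi * np.clip(tau, 0, t_sys) / t_sys), 0.0)
    lobe_mean = (2.0 / np.pi) * (t_sys / T)
    flow = table["sbf_mean"].to_numpy()[ib] / lobe_mean * lobe
    ss = np.random.SeedSequence(config.seed)
    _var_seed, p_seed, f_seed = ss.spawn(3)
    if config.noise_sd_pressure > 0:
        pressure = pressure + config.noise_sd_pressure * np.random.default_rng(
            p_seed
        ).standard_normal(n)
    if config.noise_sd_flow > 0:
        flow = flow + config.noise_sd_flow * np.random.default_rng(
            f_seed
        ).standard_normal(n)
    record = WaveformRecord(fs=fs, pressure=pressure, flow=flow)
    return record, table
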