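"""Flow-pressure spectral coupling: squared coherence and partial directed
coherence (PDC).

Spontaneous beat-to-beat fluctuations of systemic blood flow and arterial
pressure below 0.2 Hz carry the signature of tissue autoregulation.  This
module estimates

* Welch squared coherence ``C(f) = |S_xy|^2 / (S_xx S_yy)`` -- the
  frequency-resolved squared linear correlation of the two channels;
* squared PDC -- a VAR-based, direction-resolved coupling measure (a
  frequency-domain counterpart of Granger causality).  With
  ``Abar(f) = I - sum_k A_k exp(-i 2 pi f k dt)`` the squared PDC from source
  channel j to target i is ``|Abar_ij(f)|^2 / sum_m |Abar_mj(f)|^2``; this is
  the original column-normalized variant, so the outflows of each source sum
  to exactly 1 at every frequency (self-terms included).

Band summaries average over (0, 0.2] Hz (f = 0 excluded) per subject and
report the group median with a seeded percentile-bootstrap 95% CI, the
convention used for non-normally distributed coupling measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from statsmodels.tsa.vector_ar.var_model import VAR as _VAR

from .synthetic import CHANNELS, spectral_radius
from .waveform import EvenSeries, resample_even

__all__ = [
    "VarModel",
    "CouplingSpectra",
    "BandSummary",
    "CouplingConfig",
    "welch_coherence",
    "fit_var",
    "pdc",
    "var_spectrum",
    "band_summary",
    "windowed_coupling",
]

LOW_FREQUENCY_BAND = (0.0, 0.2)  # Hz; the autoregulation band


@dataclass
class VarModel:
    """Fitted bivariate VAR: lag matrices, innovation covariance, diagnostics."""

    coeffs: np.ndarray  # (p, m, m)
    noise_cov: np.ndarray  # (m, m)
    dt: float
    order: int
    ic_values: dict = field(default_factory=dict)
    whiteness: tuple | None = None  # (statistic, p-value) or None
    order_at_boundary: bool = False

    @property
    def nchan(self) -> int:
        return self.noise_cov.shape[0]

    @property
    def stable(self) -> bool:
        return spectral_radius(self.coeffs) < 1.0


@dataclass
class CouplingSpectra:
    """Coherence and/or squared PDC on a frequency grid.

    ``pdc[i, j, f]`` is the squared PDC from source channel j to target i;
    channel order follows :data:`hemodyn.synthetic.CHANNELS`.
    """

    freqs: np.ndarray
    dt: float
    coherence: np.ndarray | None = None
    pdc: np.ndarray | None = None
    channels: tuple[str, ...] = CHANNELS
    meta: dict = field(default_factory=dict)

    def band_mean(
        self,
        kind: str = "coherence",
        band: tuple[float, float] = LOW_FREQUENCY_BAND,
        source: str | None = None,
        target: str | None = None,
    ) -> float:
        """Arithmetic mean over grid points in ``(band[0], band[1]]``."""
        mask = (self.freqs > band[0]) & (self.freqs <= band[1])
        if not mask.any():
            raise ValueError(f"no frequency grid points inside band {band}")
        if kind == "coherence":
            if self.coherence is None:
                raise ValueError("no coherence stored in these spectra")
            return float(np.mean(self.coherence[mask]))
        if kind == "pdc":
            if self.pdc is None:
                raise ValueError("no PDC stored in these spectra")
            i = self.channels.index(target)
            j = self.channels.index(source)
            return float(np.mean(self.pdc[i, j, mask]))
        raise ValueError(f"unknown kind {kind!r}")


@dataclass
class BandSummary:
    """Per-subject band means with group median and bootstrap 95% CI."""

    band: tuple[float, float]
    values: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None = None


def welch_coherence(
    series: EvenSeries,
    segment_length: int = 256,
    overlap: float = 0.5,
    window: str = "hann",
) -> CouplingSpectra:
    """Welch squared coherence between the flow and pressure channels.

    Requires at least two segments after overlap (the coherence of a single
    segment is identically 1 and meaningless).  Values are clipped to [0, 1]
    against roundoff.
    """
    n = series.n
    noverlap = int(segment_length * overlap)
    step = segment_length - noverlap
    if step <= 0:
        raise ValueError("overlap fraction must leave a positive step")
    n_segments = 1 + (n - segment_length) // step if n >= segment_length else 0
    if n_segments < 2:
        raise ValueError(
            "need at least 2 Welch segments; single-segment coherence is "
            "identically 1"
        )
    if segment_length * series.dt < 100.0:
        warnings.warn(
            "segments shorter than 100 s under-resolve the 0.02 Hz end of the "
            "autoregulation band",
            stacklevel=2,
        )
    fs = 1.0 / series.dt
    freqs, coh = _signal.coherence(
        series.flow,
        series.pressure,
        fs=fs,
        window=window,
        nperseg=segment_length,
        noverlap=noverlap,
    )
    coh = np.clip(coh, 0.0, 1.0)
    return CouplingSpectra(
        freqs=freqs,
        dt=series.dt,
        coherence=coh,
        meta={
            "segment_length": segment_length,
            "overlap": overlap,
            "window": window,
            "n_segments": int(n_segments),
        },
    )


def fit_var(
    series: EvenSeries | np.ndarray,
    max_order: int = 20,
    criterion: str = "aic",
    order: int | None = None,
    dt: float | None = None,
) -> VarModel:
    """Least-squares VAR fit with information-criterion order selection.

    Fits orders ``1..max_order`` (plus 0) and keeps the criterion-minimizing
    one, unless ``order`` pins it.  The series is expected to be detrended
    (see :func:`hemodyn.waveform.resample_even`).  Refuses to return an
    unstable model; flags the order selection when it lands on the boundary
    ``max_order`` (the candidate range may be too small).
    """
    if isinstance(series, EvenSeries):
        data = series.data
        dt = series.dt
    else:
        data = np.asarray(series, dtype=float)
        if dt is None:
            raise ValueError("dt is required when passing a raw array")
    n = len(data)
    needed = 10 * (order if order is not None else max_order) * data.shape[1]
    if n < needed:
        raise ValueError(
            f"need at least {needed} samples for max order "
            f"{order if order is not None else max_order}, got {n}"
        )
    model = _VAR(data)
    ic_values: dict = {}
    boundary = False
    if order is None:
        sel = model.select_order(maxlags=max_order)
        order = int(sel.selected_orders[criterion])
        ic_values = {name: np.asarray(vals) for name, vals in sel.ics.items()}
        boundary = order == max_order
    res = model.fit(order, trend="c")
    coeffs = np.asarray(res.coefs)
    if order >= 1:
        rho = spectral_radius(coeffs)
        if rho >= 1.0:
            raise RuntimeError(
                f"fitted VAR is unstable (companion spectral radius {rho:.4f}); "
                "refusing to return it"
            )
    whiteness = None
    try:
        nlags = min(max(10, order + 1), max(order + 1, n // 10))
        if nlags > order:
            test = res.test_whiteness(nlags=nlags, adjusted=False)
            whiteness = (float(test.test_statistic), float(test.pvalue))
    except Exception:
        whiteness = None
    return VarModel(
        coeffs=coeffs,
        noise_cov=np.asarray(res.sigma_u),
        dt=float(dt),
        order=order,
        ic_values=ic_values,
        whiteness=whiteness,
        order_at_boundary=boundary,
    )


def _abar(coeffs: np.ndarray, freqs: np.ndarray, dt: float) -> np.ndarray:
    """``Abar(f) = I - sum_k A_k exp(-i 2 pi f k dt)``, shape (nf, m, m)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p = coeffs.shape[0]
    m = coeffs.shape[1] if p else 2
    eye = np.eye(m)
    if p == 0:
        return np.broadcast_to(eye, (len(freqs), m, m)).astype(complex).copy()
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) * dt)  # (nf, p)
    return eye[None, :, :] - np.einsum("fk,kij->fij", phase, coeffs)


def pdc(model, freqs: np.ndarray | None = None) -> CouplingSpectra:
    """Squared partial directed coherence of a (fitted or stated) VAR model.

    ``model`` is anything exposing ``coeffs`` (p, m, m) and ``dt``.  Column
    normalization -- the outflows of each source channel, self-term included,
    summing to 1 -- holds to machine precision at every frequency.  Raises on
    frequencies above the Nyquist limit ``1/(2 dt)``.
    """
    dt = float(model.dt)
    nyquist = 0.5 / dt
    if freqs is None:
        freqs = np.linspace(0.0, nyquist, 129)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > nyquist * (1 + 1e-12)):
        raise ValueError(f"frequencies must lie in [0, {nyquist}] Hz")
    abar = _abar(model.coeffs, freqs, dt)
    num = np.abs(abar) ** 2  # (nf, i, j)
    denom = num.sum(axis=1, keepdims=True)  # sum over targets i per source j
    squared = np.moveaxis(num / denom, 0, 2)  # (i, j, nf)
    return CouplingSpectra(freqs=freqs, dt=dt, pdc=squared)


def var_spectrum(model, freqs: np.ndarray) -> np.ndarray:
    """One-sided VAR cross-spectral matrix ``2 dt H(f) Sigma H(f)^H``.

    ``H = Abar^{-1}``.  Used as the analytic counterpart of Welch estimates on
    simulated series.
    """
    freqs = np.asarray(freqs, dtype=float)
    abar = _abar(model.coeffs, freqs, float(model.dt))
    h = np.linalg.inv(abar)
    sigma = np.asarray(model.noise_cov, dtype=float)
    s = np.einsum("fij,jk,flk->fil", h, sigma, np.conj(h))
    return 2.0 * float(model.dt) * s


def band_summary(
    spectra: Sequence,
    kind: str = "coherence",
    band: tuple[float, float] = LOW_FREQUENCY_BAND,
    source: str | None = None,
    target: str | None = None,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> BandSummary:
    """Group summary of per-subject band means.

    ``spectra`` may hold :class:`CouplingSpectra` (band means are computed
    here) or plain scalars.  The group statistic is the median; the 95% CI is
    the seeded percentile bootstrap over subjects.
    """
    values = np.array(
        [
            s.band_mean(kind=kind, band=band, source=source, target=target)
            if isinstance(s, CouplingSpectra)
            else float(s)
            for s in spectra
        ]
    )
    if len(values) < 2:
        raise ValueError("need at least 2 subjects for a confidence interval")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(int(n_boot), len(values)))
    boot_medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    return BandSummary(
        band=band,
        values=values,
        median=float(np.median(values)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=int(n_boot),
        seed=seed,
    )


@dataclass(frozen=True)
class CouplingConfig:
    """Parameters of the windowed coupling pipeline."""

    target_rate: float = 2.0
    segment_length: int = 256
    overlap: float = 0.5
    taper: str = "hann"
    max_order: int = 20
    criterion: str = "aic"
    band: tuple[float, float] = LOW_FREQUENCY_BAND
    n_boot: int = 2000
    seed: int = 0
    max_gap: float = 5.0
    #: divide each detrended channel by its SD before the VAR fit.  The
    #: original column-normalized PDC is not scale-invariant, and neither
    #: choice is neutral: raw measurement units make PDC sensitive to changes
    #: in a channel's working range (e.g. hypotension compressing pressure in
    #: mmHg), while per-window standardization makes it sensitive to changes
    #: in a channel's variance (a stronger drive inflates the reverse
    #: direction).  The default keeps the measured units.
    standardize: bool = False


WINDOW_QUANTITIES = ("coherence", "pdc_flow_to_pressure", "pdc_pressure_to_flow")


def _subject_window_measures(
    table: pd.DataFrame, lo: float, hi: float, config: CouplingConfig
) -> tuple[dict, bool]:
    """(band means, gap flag) for one subject in one window."""
    t = table["t_onset"].to_numpy(dtype=float)
    if lo < t.min() - 1e-9 or hi > t.max() + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] s extends beyond the recording "
            f"[{t.min()}, {t.max()}] s"
        )
    inside = t[(t >= lo) & (t <= hi)]
    flagged = len(inside) < 2 or float(np.max(np.diff(inside))) > config.max_gap
    series = resample_even(
        table, target_rate=config.target_rate, window=(lo, hi), detrend=True
    )
    if config.standardize:
        series = EvenSeries(
            dt=series.dt,
            flow=series.flow / np.std(series.flow),
            pressure=series.pressure / np.std(series.pressure),
            t0=series.t0,
            detrended=series.detrended + "+standardized",
        )
    coh = welch_coherence(
        series,
        segment_length=config.segment_length,
        overlap=config.overlap,
        window=config.taper,
    )
    max_order = min(config.max_order, series.n // (10 * 2))
    model = fit_var(series, max_order=max_order, criterion=config.criterion)
    spectra = pdc(model, freqs=np.linspace(0.0, 0.5 / series.dt, 201))
    values = {
        "coherence": coh.band_mean("coherence", band=config.band),
        "pdc_flow_to_pressure": spectra.band_mean(
            "pdc", band=config.band, source="flow", target="pressure"
        ),
        "pdc_pressure_to_flow": spectra.band_mean(
            "pdc", band=config.band, source="pressure", target="flow"
        ),
    }
    return values, flagged


def windowed_coupling(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    window_centers: Sequence[float],
    window_length: float,
    config: CouplingConfig | None = None,
) -> dict:
    """Coupling band summaries in analysis windows along the recording.

    For each window: resample the beat series to a uniform grid, remove the
    linear trend, estimate Welch coherence and VAR-based PDC, and average each
    over the low-frequency band.  Subjects whose window contains a beat gap
    longer than ``config.max_gap`` seconds are flagged and excluded from the
    group summary.  Returns ``{"per_subject": DataFrame, "summary":
    DataFrame}``.
    """
    if config is None:
        config = CouplingConfig()
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    rows = []
    for subject, table in enumerate(tables):
        for center in window_centers:
            lo = center - window_length / 2.0
            hi = center + window_length / 2.0
            values, flagged = _subject_window_measures(table, lo, hi, config)
            for quantity, value in values.items():
                rows.append(
                    {
                        "subject": subject,
                        "window_center": float(center),
                        "quantity": quantity,
                        "value": value,
                        "flagged": flagged,
                    }
                )
    per_subject = pd.DataFrame(rows)
    child_seeds = np.random.SeedSequence(config.seed).spawn(len(window_centers))
    summary_rows = []
    for w, center in enumerate(window_centers):
        seed_w = int(child_seeds[w].generate_state(1)[0] % (2**31 - 1))
        for quantity in WINDOW_QUANTITIES:
            sel = per_subject[
                (per_subject["window_center"] == float(center))
                & (per_subject["quantity"] == quantity)
                & (~per_subject["flagged"])
            ]
            if len(sel) < 2:
                continue
            summ = band_summary(
                sel["value"].to_list(),
                band=config.band,
                n_boot=config.n_boot,
                seed=seed_w,
            )
            summary_rows.append(
                {
                    "window_center": float(center),
                    "quantity": quantity,
                    "n_subjects": len(sel),
                    "median": summ.median,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                }
            )
    return {"per_subject": per_subject, "summary": pd.DataFrame(summary_rows)}
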