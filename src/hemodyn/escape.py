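"""Autoregulatory escape from bolus vasoconstriction.

A bolus of an alpha1-adrenergic agonist (phenylephrine) transiently raises
systemic vascular resistance; tissue autoregulation then restores resistance
("escape") within tens of seconds even though the drug persists.  This module
quantifies that escape from a per-beat SVR trace: response magnitude
(peak - baseline), the peak-normalized recovery curve (baseline = 0 %, peak =
100 %), the recovery extent at a fixed time after the peak, and the rate
constant of a one-phase exponential fit

    y(t) = plateau + (100 - plateau) * exp(-k t),      t from the peak,

with a free plateau because recovery is typically incomplete in the absence
of an inflammatory challenge.  Group comparisons use the median and a seeded
percentile-bootstrap 95% CI, the convention for these non-normal metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ResponseSegment",
    "PeakResult",
    "NormalizedCurve",
    "EscapeFit",
    "EscapeResult",
    "EscapeFitError",
    "segment_response",
    "peak_magnitude",
    "normalize_response",
    "recovery_extent",
    "fit_escape",
    "analyze_escape",
    "group_mean_curve",
    "compare_groups",
]


class EscapeFitError(RuntimeError):
    """Raised when the exponential recovery fit fails to converge."""


@dataclass
class ResponseSegment:
    """SVR trace around one bolus, re-expressed relative to the injection."""

    t: np.ndarray  # seconds relative to injection (negative = pre)
    svr: np.ndarray  # mmHg.min/mL
    baseline: float  # pre-injection mean SVR
    injection_time: float
    meta: dict = field(default_factory=dict)


@dataclass
class PeakResult:
    delta: float  # peak - baseline, mmHg.min/mL
    t_peak: float  # seconds post-injection
    truncated: bool  # peak at the window edge (response possibly cut)


@dataclass
class NormalizedCurve:
    """Response in percent of the peak rise: baseline -> 0, peak -> 100."""

    t: np.ndarray  # seconds relative to injection
    y: np.ndarray  # percent
    t_peak: float

    def from_peak(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, y) with time rebased so the peak sample sits at t = 0."""
        mask = self.t >= self.t_peak
        return self.t[mask] - self.t_peak, self.y[mask]


@dataclass
class EscapeFit:
    k: float  # 1/s
    plateau: float  # percent
    rmse: float
    converged: bool
    degenerate: bool = False
    message: str = ""
    cov: np.ndarray | None = None


@dataclass
class EscapeResult:
    """Bundle of escape metrics for one bolus in one subject."""

    segment: ResponseSegment
    delta_peak: float
    t_peak: float
    truncated: bool
    curve: NormalizedCurve
    recovery_extent: float  # percent of the peak rise recovered
    fit: EscapeFit | None


def segment_response(
    table: pd.DataFrame,
    injection_time: float,
    pre_window: float = 60.0,
    post_window: float = 120.0,
    max_gap: float = 5.0,
) -> ResponseSegment:
    """Extract the SVR trace around an injection and set its baseline.

    The baseline is the mean SVR over ``pre_window`` seconds immediately
    before the injection.  Errors if the recording does not cover the window
    or if beat gaps in the pre-window leave the baseline undefined.
    """
    if pre_window < 30.0:
        raise ValueError("need at least 30 s of pre-injection baseline")
    t = table["t_onset"].to_numpy(dtype=float)
    svr = table["svr"].to_numpy(dtype=float)
    if injection_time - pre_window < t.min() - 1e-9:
        raise ValueError("injection precedes the recording plus pre-window")
    if injection_time + post_window > t.max() + 1e-9:
        raise ValueError("post-injection window extends beyond the recording")
    mask = (t >= injection_time - pre_window) & (t <= injection_time + post_window)
    t_seg = t[mask] - injection_time
    svr_seg = svr[mask]
    pre = t_seg < 0
    if not pre.any():
        raise ValueError("no beats in the pre-injection window; baseline undefined")
    pre_times = t_seg[pre]
    gaps = np.diff(np.concatenate([pre_times, [0.0]]))
    if len(pre_times) < 2 or np.max(gaps) > max_gap:
        raise ValueError(
            "beat gaps in the pre-injection window; baseline undefined"
        )
    if np.any(~np.isfinite(svr_seg)):
        raise ValueError("undefined SVR values inside the response segment")
    baseline = float(np.mean(svr_seg[pre]))
    return ResponseSegment(
        t=t_seg,
        svr=svr_seg,
        baseline=baseline,
        injection_time=float(injection_time),
        meta={"pre_window": pre_window, "post_window": post_window},
    )


def peak_magnitude(segment: ResponseSegment) -> PeakResult:
    """Peak rise of SVR above baseline within the post-injection window.

    Ties are broken by the earliest time; a peak at the window edge is flagged
    as possibly truncated.
    """
    post = segment.t >= 0
    if not post.any():
        raise ValueError("segment contains no post-injection samples")
    rise = segment.svr[post] - segment.baseline
    i = int(np.argmax(rise))  # argmax returns the earliest maximum
    return PeakResult(
        delta=float(rise[i]),
        t_peak=float(segment.t[post][i]),
        truncated=i == len(rise) - 1,
    )


def normalize_response(segment: ResponseSegment) -> NormalizedCurve:
    """Percent-of-peak normalization: baseline maps to 0, the peak to 100.

    The peak sample equals exactly 100 by construction.  Raises when the peak
    rise is not positive (nothing to normalize).
    """
    peak = peak_magnitude(segment)
    if peak.delta <= 0:
        raise ValueError("peak SVR rise is not positive; nothing to normalize")
    # ratio first: the peak sample divides by itself, so it is exactly 1.0
    y = 100.0 * ((segment.svr - segment.baseline) / peak.delta)
    return NormalizedCurve(t=segment.t.copy(), y=y, t_peak=peak.t_peak)


def recovery_extent(curve: NormalizedCurve, at: float = 90.0) -> float:
    """Percent of the peak rise recovered ``at`` seconds after the peak.

    Reads the normalized curve by interpolation; if the curve ends earlier,
    the last value is used (the read-out time is clamped).
    """
    t_rel, y = curve.from_peak()
    return float(100.0 - np.interp(at, t_rel, y))


def _exp_model(t, k, plateau):
    return plateau + (100.0 - plateau) * np.exp(-k * t)


def fit_escape(t: np.ndarray, y: np.ndarray) -> EscapeFit:
    """One-phase exponential fit of a peak-normalized recovery curve.

    ``t`` starts at the peak (t[0] = 0, y[0] ~ 100) and must contain at least
    10 samples.  A flat curve is reported as a degenerate fit (k ~ 0,
    rate unidentifiable) rather than an arbitrary number; non-convergence
    raises :class:`EscapeFitError` with diagnostics.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-peak samples to fit")
    if abs(t[0]) > 1e-9:
        raise ValueError("time axis must start at the peak (t[0] = 0)")
    if np.ptp(y) < 1e-6:
        return EscapeFit(
            k=0.0,
            plateau=float(np.mean(y)),
            rmse=float(np.std(y)),
            converged=False,
            degenerate=True,
            message="flat curve: recovery rate unidentifiable",
        )
    plateau0 = float(np.min(y))
    half_level = 0.5 * (100.0 + plateau0)
    below = np.nonzero(y <= half_level)[0]
    t_half = t[below[0]] if len(below) and t[below[0]] > 0 else t[-1] / 3.0
    k0 = np.log(2.0) / max(t_half, 1e-6)
    try:
        popt, pcov = curve_fit(
            _exp_model, t, y, p0=(k0, plateau0), method="lm", maxfev=20000
        )
    except RuntimeError as exc:
        raise EscapeFitError(
            f"exponential recovery fit did not converge (p0=({k0:.4g}, "
            f"{plateau0:.4g})): {exc}"
        ) from exc
    k, plateau = (float(v) for v in popt)
    resid = y - _exp_model(t, k, plateau)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if k <= 0:
        return EscapeFit(
            k=k,
            plateau=plateau,
            rmse=rmse,
            converged=True,
            degenerate=True,
            message="non-positive rate constant: no escape detected",
            cov=pcov,
        )
    return EscapeFit(k=k, plateau=plateau, rmse=rmse, converged=True, cov=pcov)


def analyze_escape(
    table: pd.DataFrame,
    injection_time: float,
    pre_window: float = 60.0,
    post_window: float = 120.0,
    recovery_at: float = 90.0,
    fit: bool = True,
) -> EscapeResult:
    """Full escape analysis of one bolus: segment, peak, normalize, fit."""
    segment = segment_response(
        table, injection_time, pre_window=pre_window, post_window=post_window
    )
    peak = peak_magnitude(segment)
    curve = normalize_response(segment)
    extent = recovery_extent(curve, at=recovery_at)
    escape_fit = None
    if fit:
        t_rel, y = curve.from_peak()
        escape_fit = fit_escape(t_rel, y)
    return EscapeResult(
        segment=segment,
        delta_peak=peak.delta,
        t_peak=peak.t_peak,
        truncated=peak.truncated,
        curve=curve,
        recovery_extent=extent,
        fit=escape_fit,
    )


def group_mean_curve(
    curves: Sequence[NormalizedCurve], grid_dt: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean normalized curve on a common post-peak grid.

    Subject curves (already peak-normalized: subject-first normalization) are
    interpolated from their peaks onto a shared grid and averaged.  The grid
    extends to the shortest subject's coverage.
    """
    if not curves:
        raise ValueError("no curves to average")
    rebased = [c.from_peak() for c in curves]
    t_end = min(t[-1] for t, _ in rebased)
    grid = np.arange(0.0, t_end + 1e-9, grid_dt)
    stack = np.vstack([np.interp(grid, t, y) for t, y in rebased])
    return grid, stack.mean(axis=0)


_METRICS = ("delta_peak", "recovery_extent", "k")


def compare_groups(
    groups: Mapping[str, Sequence[EscapeResult]],
    metrics: Sequence[str] = _METRICS,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-group medians with percentile-bootstrap 95% CIs for escape metrics.

    Metrics: ``delta_peak`` (mmHg.min/mL), ``recovery_extent`` (%), and the
    per-subject rate constant ``k`` (1/s).  Requires at least two subjects per
    group.
    """
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for name, results in groups.items():
        if len(results) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(results) < 2:
            raise ValueError(f"group {name!r} needs at least 2 subjects")
        for metric in metrics:
            if metric == "k":
                values = np.array(
                    [r.fit.k for r in results if r.fit is not None and not r.fit.degenerate]
                )
            else:
                values = np.array([getattr(r, metric) for r in results])
            if len(values) < 2:
                continue
            idx = rng.integers(0, len(values), size=(int(n_boot), len(values)))
            boots = np.median(values[idx], axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "group": name,
                    "metric": metric,
                    "n": len(values),
                    "median": float(np.median(values)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
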