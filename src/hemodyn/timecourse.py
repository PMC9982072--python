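"""Time-course summaries: flow-pressure regression and phase detection.

Two transparent proxies of how the circulation is being regulated:

* ordinary least-squares regression of beat-mean flow (SBF_mean) on beat-mean
  pressure (AP_mean) inside an analysis window -- a slope near zero with low
  R^2 is the signature of autoregulated (pressure-independent) flow, while a
  proportional flow-pressure relation marks a passive circuit;
* a baseline-SD rule that flags contiguous epochs in a binned time course
  where a variable departs from its pre-challenge baseline by more than a
  threshold number of baseline standard deviations for a minimum number of
  consecutive bins.  Epochs are labeled by the joint direction pattern of
  resistance and flow, which is what distinguishes the three hemodynamic
  phases of the endotoxin response.  Thresholds are expressed in baseline-SD
  units, so the rule is invariant to rescaling the measurement units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowPressureFit",
    "PhaseWindow",
    "PhaseReport",
    "flow_pressure_regression",
    "detect_phases",
]


@dataclass
class FlowPressureFit:
    """OLS fit of SBF_mean on AP_mean over beats inside a window."""

    window: tuple[float, float]
    slope: float  # mL/min per mmHg
    intercept: float  # mL/min
    r_squared: float
    n: int


@dataclass
class PhaseWindow:
    """One detected epoch: its span and per-variable direction/magnitude."""

    start: float  # s
    end: float  # s
    directions: dict  # variable -> "up" | "down" | "unchanged"
    magnitudes: dict  # variable -> mean percent change from baseline


@dataclass
class PhaseReport:
    epochs: list
    baseline: dict = field(default_factory=dict)  # variable -> (mean, sd)
    bin_width: float = float("nan")

    @property
    def no_change(self) -> bool:
        return len(self.epochs) == 0


def flow_pressure_regression(
    table: pd.DataFrame, window: tuple[float, float]
) -> FlowPressureFit:
    """OLS of beat-mean flow on beat-mean pressure inside ``window``.

    Requires at least 10 beats and non-zero pressure variance.  A constant
    flow gives slope 0 and R^2 = 0 (perfect autoregulation limit); exactly
    proportional flow gives R^2 = 1 (passive-circuit limit).
    """
    lo, hi = window
    t = table["t_onset"].to_numpy(dtype=float)
    mask = (t >= lo) & (t < hi)
    x = table["ap_mean"].to_numpy(dtype=float)[mask]
    y = table["sbf_mean"].to_numpy(dtype=float)[mask]
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 beats in the window, got {n}")
    if np.var(x) == 0:
        raise ValueError("pressure variance is zero inside the window; slope undefined")
    design = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = (float(b) for b in beta)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if ss_tot <= 0 else 1.0 - ss_res / ss_tot
    return FlowPressureFit(
        window=(float(lo), float(hi)),
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        n=n,
    )


def _run_filter(states: np.ndarray, min_bins: int) -> np.ndarray:
    """Zero out runs of identical non-zero state shorter than ``min_bins``."""
    out = states.copy()
    n = len(states)
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        if states[i] != 0 and (j - i) < min_bins:
            out[i:j] = 0
        i = j
    return out


def detect_phases(
    binned: pd.DataFrame,
    baseline_window: tuple[float, float],
    variables: Sequence[str] = ("svr", "sbf_mean"),
    threshold_sd: float = 2.0,
    min_bins: int = 2,
    segment_variable: str = "svr",
) -> PhaseReport:
    """Flag contiguous departure epochs in a binned time course.

    A bin departs when its value falls outside ``baseline mean +/-
    threshold_sd * baseline SD``; a departure must persist for at least
    ``min_bins`` consecutive bins to count.  Epochs are maximal runs of bins
    in which at least one variable departs and the direction of
    ``segment_variable`` (vascular resistance by default, since the
    hemodynamic phases are resistance-defined) stays constant; each epoch is
    labeled by the majority direction of every variable inside it.  Needs at
    least 3 baseline bins.
    """
    if threshold_sd == 0:
        warnings.warn(
            "threshold of 0 SD flags every bin; the policy is degenerate",
            stacklevel=2,
        )
    centers = binned["t_center"].to_numpy(dtype=float)
    if len(centers) < 2:
        raise ValueError("binned time course too short")
    bin_width = float(np.median(np.diff(centers)))
    b0, b1 = baseline_window
    base_mask = (centers >= b0) & (centers < b1)
    if base_mask.sum() < 3:
        raise ValueError("need at least 3 baseline bins")
    post_mask = centers >= b1
    post_centers = centers[post_mask]
    baseline_stats: dict = {}
    states = {}
    for var in variables:
        vals = binned[var].to_numpy(dtype=float)
        base_vals = vals[base_mask & np.isfinite(vals)]
        mean = float(np.mean(base_vals))
        sd = float(np.std(base_vals, ddof=1))
        baseline_stats[var] = (mean, sd)
        post_vals = vals[post_mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (post_vals - mean) / sd if sd > 0 else np.where(
                post_vals == mean, 0.0, np.inf * np.sign(post_vals - mean)
            )
        state = np.where(np.isfinite(z) & (np.abs(z) > threshold_sd), np.sign(z), 0.0)
        state = np.where(np.isfinite(post_vals), state, 0.0)
        states[var] = _run_filter(state.astype(int), min_bins)
    if segment_variable not in states:
        raise ValueError(f"segment_variable {segment_variable!r} not among variables")
    joint = np.stack([states[var] for var in variables], axis=1)
    active = np.any(joint != 0, axis=1)
    seg_state = states[segment_variable]
    epochs: list[PhaseWindow] = []
    labels = {1: "up", -1: "down", 0: "unchanged"}
    i = 0
    n = len(post_centers)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j] and seg_state[j] == seg_state[i]:
            j += 1
        directions = {}
        magnitudes = {}
        for var in variables:
            mean, _sd = baseline_stats[var]
            vals = binned[var].to_numpy(dtype=float)[post_mask][i:j]
            vals = vals[np.isfinite(vals)]
            magnitudes[var] = (
                float(100.0 * (np.mean(vals) - mean) / mean) if len(vals) else float("nan")
            )
            run = states[var][i:j]
            counts = {s: int(np.sum(run == s)) for s in (-1, 0, 1)}
            directions[var] = labels[max(counts, key=counts.get)]
        epochs.append(
            PhaseWindow(
                start=float(post_centers[i] - bin_width / 2.0),
                end=float(post_centers[j - 1] + bin_width / 2.0),
                directions=directions,
                magnitudes=magnitudes,
            )
        )
        i = j
    return PhaseReport(epochs=epochs, baseline=baseline_stats, bin_width=bin_width)
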