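# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic recordings

The generator emulates hemodynamic recordings from an unanesthetized rat:
two channels (arterial pressure in mmHg, ascending-aortic flow in mL/min)
sampled at 500 Hz. It is built from four layers.

**Pulse shapes.** Each beat is a fast systolic upstroke (quarter-period
half-sine over 12 % of the beat) followed by an exponential diastolic decay
whose time constant is one fifth of the remaining beat, so the pressure
returns close to the diastolic foot before the next onset. The flow channel
is a systolic ejection lobe (half-sine over 35 % of the beat) with zero
diastolic flow. These are the simplest shapes with a well-defined dP/dt_max
(the upstroke's peak slope, `PP·π/(2·T_rise)`) and analytically known
per-beat means; the diastolic and systolic levels of every beat are solved
so that the per-beat time-average equals the target mean pressure exactly.

**Slow fluctuations.** Spontaneous beat-to-beat variability is a stable
bivariate VAR process on its own 2 Hz clock, sampled at beat onsets and
applied as fractional modulation of the per-beat means. Running the VAR on a
fixed slow clock keeps the coupling spectrum controlled independently of
heart rate. The default process is a VAR(2) in which flow drives pressure
(cross-lags 0.35 and 0.08) with a weak passive return path (0.05), innovation
SDs of about 2 % — the directed asymmetry expected when the regulated
variable (flow) leads the adjustments of the other. Stability is enforced at
construction (companion spectral radius < 1, reported in the error when
violated). An optional `coupling_boost` multiplies the flow→pressure
cross-lags inside a stated time span, with the process state carried
continuously across the joins.

**Phase schedule.** Slow trends are multiplicative epochs on flow (SBF) and
resistance (SVR); the pressure multiplier is always their product, so the
per-instant identity `MAP = SVR × SBF` holds exactly, including during the
linear transition ramps (default 120 s — transitions are gradual but no
functional form is canonical, so the simplest was chosen). The packaged
three-phase endotoxin-like schedule is: 10 min baseline; 20 min with flow
−22 % and resistance up so pressure holds; 40 min with resistance at 0.6×
and flow back at baseline (pressure −40 %, i.e. a ~55 mmHg nadir from the
92 mmHg baseline); 50 min with a resistance overshoot (1.25×) restoring
pressure while flow falls again.

**Boluses.** A vasoconstrictor bolus multiplies SVR by a linear rise to the
peak (default 10 s) followed by exponential recovery at rate `k` toward a
plateau retaining a stated fraction of the peak rise. Mean pressure follows
the square root of the SVR multiplier — splitting the response between a
pressure rise and a flow fall, as observed for alpha-adrenergic boluses —
and flow is recomputed from the identity. Overlapping boluses and events
outside the recorded span are rejected.

Baselines: MAP 92 mmHg, SBF 110 mL/min (SVR ≈ 0.84 mmHg·min/mL), heart rate
360 bpm, pulse pressure 40 mmHg. Measurement noise is additive Gaussian on
the waveforms only (SD 1 mmHg / 2 mL·min⁻¹, small relative to the signals);
ground-truth beat tables are noise-free, which is what makes the
conservation identities testable to machine precision. All randomness flows
from one integer seed through `numpy.random.SeedSequence`.

### What the generator does not emulate

Closed-loop baroreflex feedback, respiratory and Mayer-wave rhythms beyond
the VAR structure, heart-rate variability (the beat clock is constant within
a recording), arrhythmia, motion artifacts, and device-specific filtering.
Passing tests therefore demonstrate that the estimators recover known ground
truth under controlled coupling and kinetics — not that they are robust to
every artifact of in-vivo recordings.

## Beat detection and per-beat hemodynamics

Beat onsets are diastolic troughs: candidate troughs are found on a
zero-phase 20 Hz low-pass copy of the pressure channel (4th-order
Butterworth, refractory distance of one beat at the maximum plausible heart
rate, prominence 25 % of the pulse amplitude), then each onset is refined by
anchoring on the steepest systolic upstroke nearby and walking back on the
raw channel to the waveform foot. The walk-back is exact on noise-free
signals (the foot is the global in-beat minimum) and much more stable under
noise than a raw argmin, because the upstroke slope (thousands of mmHg/s)
dwarfs the noise while the late-diastolic tail is nearly flat; residual
onset jitter of a few milliseconds survives in noisy recordings and
propagates into per-beat flow means at the percent level.

Per-beat quantities over half-open intervals `[onset_i, onset_{i+1})`:
time-averaged AP_mean and SBF_mean; in-beat extrema as systolic/diastolic;
dP/dt_max as the maximum central-difference derivative of the unfiltered
pressure; HR = 60/duration; SV = SBF_mean/HR; SVR = AP_mean/SBF_mean
(central venous pressure is not recorded and is neglected). Beats with
non-positive mean flow get an undefined (NaN) SVR rather than a fabricated
value. The discrete derivative underestimates the analytic peak slope by a
few percent at 500 Hz; dP/dt_max is therefore treated as an index, not an
absolute calibration.

## Spectral coupling

Beat series are linearly interpolated onto a uniform 2 Hz grid (ample margin
over the 0–0.2 Hz band of interest) and linearly detrended per analysis
window — without detrending, the nonstationary challenge trends dominate the
spectrum as f → 0.

**Coherence** uses Welch averaging: Hann taper, 256-sample segments (128 s,
resolving ~0.008 Hz), 50 % overlap. A single segment is refused (its
coherence is identically 1); segments shorter than 100 s trigger a warning
because they under-resolve the 0.02 Hz end of the band.

**VAR fitting** is multivariate least squares with AIC order selection over
1..20 by default (BIC etc. selectable); the fit refuses to return an
unstable model, reports a residual-whiteness portmanteau test when
computable, and flags order selection that lands on the boundary of the
candidate range. A fit requires at least 10 samples per parameter per
channel.

**PDC** is the original column-normalized squared variant, computed directly
from `Ā(f) = I − Σ_k A_k e^(−i2πfkΔt)`. The column normalization
(`Σ_i |π_ij|² = 1` per source, self-terms included) holds to machine
precision by construction. Original PDC is *not* invariant to channel
scaling, and no choice of scaling is neutral: computing on raw measurement
units makes PDC sensitive to changes in a channel's working range (e.g.
hypotension compressing pressure expressed in mmHg), whereas standardizing
each channel per window makes it sensitive to changes in a channel's
variance (a stronger drive into a channel inflates the apparent reverse
coupling after renormalization). The windowed pipeline defaults to raw units
(`CouplingConfig.standardize = False`) and exposes the alternative; analyses
that compare windows across strong level changes should keep the comparison
within one convention and read direction *contrasts*, not absolute values.

**Band summaries** average over grid frequencies in (0, 0.2] Hz (f = 0
excluded) per subject; groups are summarized as the median with a seeded
percentile-bootstrap 95 % CI (2000 resamples by default) over subjects —
the convention for these non-normally distributed measures. Windows
containing beat gaps longer than 5 s are flagged and excluded from group
summaries. Analysis windows must avoid straddling schedule transitions: a
ramp or a coupling change inside one window produces spurious
cross-coupling.

## Vasoconstrictor escape

The SVR trace around an injection is re-expressed relative to the injection
time with the baseline defined as the mean over 60 s immediately
pre-injection (at least 30 s required; gaps invalidate the baseline). The
peak is the maximum rise within the post window (default 120 s), earliest
sample on ties, flagged when it sits at the window edge (possible
truncation). Normalization maps baseline to 0 % and the peak sample to
exactly 100 %; the recovery extent is read at 90 s post-peak by default
(configurable — no canonical read-out time exists). The exponential fit
`y(t) = plateau + (100 − plateau)e^(−kt)` runs from the peak sample onward
with a free plateau, because recovery is typically incomplete without an
inflammatory challenge; it is solved by Levenberg–Marquardt with a
log-half-life starting guess, raises on non-convergence (never silent
defaults), and reports flat curves as degenerate (rate unidentifiable)
rather than inventing a rate. Subject curves are normalized first and then
averaged for group-mean fitting (normalizing the group mean instead is
also possible; subject-first is the default because it weights subjects
equally regardless of response magnitude). Group comparisons bootstrap the
median per metric (peak ΔSVR, recovery extent, per-subject k).

## Time-course summaries

Binned time courses are 1-min means per variable with percent change from a
pre-challenge baseline window; empty bins stay missing. The flow-on-pressure
regression is ordinary least squares of SBF_mean on AP_mean over the beats
of a window (closed-form normal equations; R² defined as 0 when the flow
variance is 0): a slope near zero with low R² is the autoregulation
signature, a proportional relation the passive-circuit limit. Note that when
slow flow fluctuations *drive* pressure (the generator's default coupling),
the beat-to-beat regression picks up that coupling; the flat-slope signature
appears where pressure moves with flow held constant, e.g. across the
hypotension transitions.

Phase detection replaces hypothesis-testing machinery with a transparent
baseline-SD rule: a bin departs when outside baseline mean ± 2 SD (of the
binned baseline values), departures must persist for at least 2 consecutive
bins, and epochs are maximal runs of departing bins over which the
*resistance* direction is constant — the hemodynamic phases are
resistance-defined — labeled with each variable's majority direction and
mean percent change. Thresholds in baseline-SD units make the rule invariant
to unit rescaling. With 120 s ramps and 1-min bins, detected boundaries land
within about one bin of the generating schedule; a mixed-effects analysis of
real cohorts is deliberately out of scope (available off the shelf).

## Experiment sizes

The packaged experiments (`hemodyn.experiments`, also behind
`scripts/acceptance.py`) use: 20 seeds × 10,000 samples for PDC estimation
accuracy; 20,000 samples for the coherence closed form; 50 cohorts of 9
subjects (the typical group size for these coupling analyses) with 10-min
windows for directionality detection; 100 seeds at 3 percentage points of
noise for escape recovery; and 50 runs of the full 2-h schedule for phase
recovery. These sizes give stable rates while keeping a full re-run in the
low minutes on one CPU.

## Known limitations

* Constant within-recording heart rate: no baroreflex-mediated HR dynamics,
  so stroke volume and flow are proportional within a recording.
* Original PDC's scale sensitivity (above) means absolute PDC levels are
  convention-dependent; only within-convention contrasts are interpretable.
* The escape fit assumes a single exponential; biphasic recoveries will show
  structured residuals (the RMSE and residual diagnostics expose this).
* Welch coherence has a positive finite-sample bias at low segment counts;
  the defaults keep at least ~7 segments per 10-min window.
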