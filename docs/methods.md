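# Methods

## Model

The pacemaker is the classic two-process light-driven limit-cycle model of
the human circadian system, with the photic input expressed in circadian
stimulus (CS) units.

**Stimulus.** Light series carry one of three units: photopic illuminance
(lux), circadian light (CL_A, spectrally weighted irradiance), or circadian
stimulus. CS is a compressive sigmoid of CL_A,

    CS = A · [1 − 1/(1 + (CL_A/c₁)^c₂)],

with asymptote A = 0.7, half-saturation c₁ = 355.7 and steepness
c₂ = 1.1026. The sigmoid constants are configuration values
(`CSTransformParams`), never hard-coded in computation paths, so revised
calibrations of the CS model can be expressed without code changes. Lux
carries no spectral information, so lux → CL_A (and lux → CS) is rejected as
uncomputable; CL_A-only recordings can be processed in CL_A or CS mode.

**Process L.** Light activates a pool of ready retinal elements at rate
α(I) = α₀ (I/I₀)^p per minute; the used fraction n follows
ṅ = 60·[α(I)(1 − n) − β n] per hour. The saturation constant I₀ pairs with
the input unit: 9500 for lux and CL_A, and the CS asymptote 0.7 in CS mode,
so the ratio I/I₀ driving Process L is bounded in [0, 1). The photic drive
is B̂ = G·α(I)(1 − n). Disabling Process L ("bypass") freezes the adaptation
term (1 − n) at 1, so light feeds Process P directly as B = G·α(I) in the
same drive units; this isolates the dynamic (hysteresis) component while
leaving the static compression of α(·) in place. The sensitivity modulator
(1 − 0.4x)(1 − 0.4x_c) is toggled independently.

**Process P.** Van der Pol-type oscillator

    ẋ   = (π/12)[x_c + B + μ(x/3 + 4x³/3 − 256x⁷/105)]
    ẋ_c = (π/12)[q·B·x_c − x((24/(0.99669·τₓ))² + k·B)]

with μ = 0.13, q = 0.33, k = 0.55, τₓ = 24.2 h. The fixed 0.99669 factor
compensates the period lengthening introduced by the stiffness term; the
simulated dark free-run period measures 24.186 h, within 0.015 h of τₓ.
G = 33.75 is treated as derived from α₀ and β and is held fixed during
parameter sweeps, as is I₀ (an asymptote of the input metric, not a free
parameter).

**Markers.** CBT_min is the time of each cycle's minimum of x, refined by
quadratic interpolation around the discrete minimum; an optional lag
parameter (default 0, range [0, 2] h) absorbs conventions that place
CBT_min ~1 h after the x-minimum. DLMO = CBT_min − 7 h (configurable).
Phase differences are wrapped to (−12, +12] with delays positive; the ±12 h
boundary maps to +12.

**Initialization.** The dim-light limit cycle is computed once per
parameter set (100-cycle dark burn-in; final cycle stored at 1-min
resolution, anchored at the x-minimum) and cached. Initializing at an
assumed CBT_min clock time places the state on that cycle so the next
x-minimum falls at the requested clock time; if the requested time
coincides with the start instant, the minimum is placed one full day ahead
so that it is observable in the simulated span. The Process L pool starts
at its fixed point α/(α + β) for the first light sample (0 in darkness).

## Prediction and evaluation

Per subject: initialize at the assumed CBT_min, integrate the baseline
series, take the DLMO of the last baseline cycle as predicted baseline
phase, continue the integration through the intervention series, take the
last intervention DLMO, and report ΔDLMO as the wrapped difference. An
alternative re-initialization mode (restart on the limit cycle at the
end-of-baseline CBT_min) agrees with continuous chaining to < 0.1 h and
exists to document that the choice is immaterial. Intervention series
anchored to their own file timeline are shifted by whole days to follow the
baseline, preserving clock times.

Cohort metrics: per-subject signed error (predicted − observed ΔDLMO,
wrapped), MAE, percentage of subjects with |error| < 1 h, and R² defined as
the squared Pearson correlation of predicted vs observed ΔDLMO (undefined —
reported as NaN, never 0 — for n < 2 or degenerate variance). The
initial-phase sweep (default 0300–0900 in 1-h steps) selects the optimum by
maximum percentage within 1 h, ties broken by lower MAE, then earlier
clock time. Parameter sweeps validate requested grids against the published
ranges (α₀ 0.01–0.19, β 0.0025–0.02, p 0.1–1.0, μ 0.01–0.30, q 0.15–1.00,
k 0.15–0.95) unless explicitly overridden.

## Numerics

The light drive is a zero-order hold at the recorded sampling interval.
Gaps longer than 15 min hold the last value for 15 min and are then filled
with darkness (logged); the policy can be disabled for exactly
piecewise-constant synthetic inputs. Consecutive equal drive values are
merged into one segment.

Integration uses an adaptive Dormand–Prince 4(5) pair implemented
in-package with a scalar (plain-float) inner loop: the drive's piecewise
constancy means thousands of segment boundaries per subject-week, and
restarting a general-purpose solver at each boundary dominates runtime.
The integrator restarts at every segment boundary (no sample is stepped
over), caps the step at 0.1 h so the recorded trajectory has ≤ 6-min
resolution, and uses rel_tol 1e-6 / abs_tol 1e-8 by default. n is clipped
to [0, 1] at solver tolerance. |x| or |x_c| exceeding 5 (limit-cycle
amplitude is O(1)) raises an integration error, as does overflow at the
minimal step. Correctness is cross-checked in the tests against scipy's
RK45 on constant-light segments (agreement ~1e-5 over 2 days) and against
a brute-force 0.5-s forward-Euler oracle over 5 days of synthetic light
(agreement < 1e-3 in x).

PRC simulation: the oscillator starts on the dark limit cycle, free-runs
one lead-in cycle, receives the pulse(s) centered at the requested phase
relative to CBT_min (wrapped to (−12, +12], so a 24-h shifted phase grid
reproduces the curve exactly) on consecutive free-run cycles, and free-runs
a ≥ 2-cycle washout. The shift is the difference of final CBT_min times
between the treatment run and an unstimulated control run sharing all other
settings, wrapped modulo the free-run period; the control subtraction
removes free-run drift exactly.

## Synthetic data

The generator emulates body-worn light-logger (Daysimeter-like) field
recordings: 30–180 s storage intervals, a wake/sleep schedule with
day-to-day jitter (SD 0.25 h), right-skewed daytime light (lognormal
multiplicative noise, σ = 0.3 log units — field light exposure is
right-skewed; no distribution is published for these cohorts), darkness
during sleep, and timed interventions that overwrite the ambient level.
Presets follow the published field protocols: morning blue light 2 h at
CS 0.5 with orange-filtered evenings (advance), the mirrored delay
protocol, 1 h of ~225 lux blue light after waking (~CS 0.4), and 3-h
morning blue-light goggles at CS 0.5 with orange evenings from 17:00.
Orange-filtered light is modeled as CS 0.02.

The default cohort emulates the delayed-sleep young-adult studies: wake
09:00, sleep 01:00, ambient waking exposure CS 0.05 at eye level, 5-day
baseline followed by a 7-day intervention. The ambient level is a
plausible stand-in — absolute indoor exposures are not published for these
cohorts — chosen dim enough that a 5-day baseline leaves the oscillator
only partially entrained. This is a structural requirement, not a
convenience: a design-stage sensitivity analysis showed that a 2-week
bright baseline entrains completely and erases the influence of the
initial circadian phase, which would make chronotype both irrelevant and
unrecoverable, contrary to the central role initial CBT_min plays in field
cohorts.

Cohort observations are generated from the model itself: per subject, a
chronotype (initial CBT_min) is drawn, the model produces true baseline
and post-intervention DLMOs, and Gaussian noise (default SD 0.25 h) is
added to the true ΔDLMO — on ΔDLMO rather than the two DLMO times
separately, because the evaluation operates on phase changes and absolute
DLMO values carry no information here. All generators are pure functions
of their specification including the seed.

What passing tests on such cohorts do and do not show: they verify the
pipeline end to end (self-consistency at zero noise is exact by
construction), the recoverability of generating conditions, and the
directional effects of ablations and masking. They do not validate the
model against human physiology: real cohorts add sensor calibration error,
non-photic phase drives, inter-individual parameter variation, and
model-misspecification error, none of which the generator emulates.
Chronotype recovery on the default cohort (n = 20, noise SD 0.25 h, 1-h
grid) is intrinsically stochastic: the per-hour prediction bias
(~0.17 h/h) is comparable to the sampling variability of the cohort noise
median, so recovery succeeds for most but not all noise realizations.

## Problem sizes

Default experiment sizes were chosen so the whole suite runs in well under
a minute of integration time: cohorts of 3–20 subjects with 5 + 7 day
recordings at 180-s sampling, PRCs on 24-phase grids with 1–3 pulse
cycles, and oracle comparisons over 2–5 days. All are configurable upward.

## Known limitations

- The spectral phototransduction model computing CL_A from spectral power
  distributions is out of scope; CL_A/CS inputs are taken as recorded.
- No non-photic (sleep/wake) drive; predictions for blind subjects or
  strong behavioral zeitgebers are outside the model's scope.
- The CBT_min → DLMO offset is a fixed configurable constant, not a
  per-subject quantity.
- Sweeps hold G fixed while α₀ and β vary, following the convention that
  G is derived from them; no re-derivation rule is applied.
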