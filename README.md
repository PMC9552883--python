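# csoscillator

Simulation and evaluation toolkit for predicting light-induced shifts of
human circadian phase from wearable light-exposure recordings.

## The problem

The master circadian clock in the suprachiasmatic nuclei (SCN) is entrained
by retinal light exposure. Predicting how a given light history will shift a
person's circadian phase — measured in practice as the change in dim light
melatonin onset, ΔDLMO — matters for shift work, jet lag, and light-therapy
interventions for delayed sleep phase.

This package implements the classic limit-cycle pacemaker model of the human
clock with the photic input expressed as **circadian stimulus (CS)**, a
retina-grounded effective-light metric, instead of photopic illuminance:

- **CS transform.** Circadian light CL_A is compressed through a sigmoid
  `CS = A·[1 − 1/(1 + (CL_A/c₁)^c₂)]` with asymptote `A = 0.7`,
  half-saturation `c₁ = 355.7` and exponent `c₂ = 1.1026`.
- **Process L** (dynamic stimulus processor). Light `I` activates a pool of
  ready elements at rate `α(I) = α₀ (I/I₀)^p` (per minute); the used
  fraction `n` obeys `ṅ = 60[α(I)(1 − n) − βn]` (per hour), producing
  light-history dependence (hysteresis). The photic drive is
  `B̂ = G·α(I)(1 − n)`, optionally multiplied by the phase-dependent
  sensitivity modulator `(1 − 0.4x)(1 − 0.4x_c)`.
- **Process P** (pacemaker). A van der Pol-type limit-cycle oscillator:

  ```
  ẋ   = (π/12)[x_c + B + μ(x/3 + 4x³/3 − 256x⁷/105)]
  ẋ_c = (π/12)[qBx_c − x((24/(0.99669·τₓ))² + kB)]
  ```

  with μ = 0.13, q = 0.33, k = 0.55, intrinsic period τₓ = 24.2 h.
  The minimum of `x` is identified with the core body temperature minimum
  (CBT_min), and `DLMO = CBT_min − 7 h`. Phase delays are positive.

On top of the oscillator the package provides the full evaluation machinery:
per-subject ΔDLMO prediction (baseline → intervention chaining), cohort
accuracy metrics (MAE, % of subjects within 1 h, R²), initial-CBT_min sweeps
(chronotype), morning-window light masking, parameter sweeps over the
published ranges, phase response curve (PRC) simulation, and a synthetic
generator for Daysimeter-like wearable light recordings with known ground
truth.

## Worked example

Fit the model's one free quantity — the assumed initial CBT_min clock time —
to a synthetic cohort whose observations were generated by the model at a
true initial CBT_min of 05:00 plus 0.25 h observation noise:

```python
from csoscillator import CSOscillatorModel, ModelConfig
from csoscillator.synth import CohortSpec, generate_cohort

cfg = ModelConfig()                      # CS input, Process L + modulator on
spec = CohortSpec(n_subjects=8, true_init_cbt_min=5.0, obs_noise_sd=0.25, seed=7)
cohort = generate_cohort(spec, cfg)

model = CSOscillatorModel(cohort, cfg)
res = model.fit(init_grid=(3.0, 4.0, 5.0, 6.0, 7.0))
print(res.summary())
```

```
Circadian phase-shift prediction (CS-oscillator)
====================================================
Subjects:              8
Input unit:            cs
Process L:             on
Sensitivity modulator: on
Optimal init CBT_min:  05:00
----------------------------------------------------
MAE:                   0.15 h
Subjects < 1 h error:  100 %
R^2:                   0.56
----------------------------------------------------
Init sweep (pct within 1 h is the selection criterion):
 init_cbt_min  mae  pct_within_1h   r2  n_subjects
         3.00 0.60         100.00 0.59           8
         4.00 0.32         100.00 0.58           8
         5.00 0.15         100.00 0.56           8
         6.00 0.16         100.00 0.55           8
         7.00 0.26         100.00 0.53           8
```

The sweep recovers the generating chronotype (05:00) — the MAE at the
optimum (0.15 h) reflects only the injected observation noise — and the
per-init MAE column shows how a wrong initial-phase assumption degrades
prediction, mirroring the importance of chronotype in field cohorts.

The same workflows are available from the shell:

```bash
csoscillator synth --n-subjects 8 --true-init 05:00 --noise-sd 0.25 --seed 7 --out cohort/
csoscillator sweep-init --cohort cohort/cohort.csv --grid 3,4,5,6,7 --out sweep/
csoscillator prc --level 0.5 --duration 6 --out prc/
```

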