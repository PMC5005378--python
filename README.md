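# circasleep

Analysis pipeline for rodent sleep and circadian electrophysiology under
shortened light–dark cycles (e.g. LD12/12 → LD11/11 → DD → LD10.5/10.5 →
LD10/10), together with a synthetic-data generator that embodies every
statistical structure the analyses assume — so the whole chain can be
validated end-to-end against known ground truth.

It is written for sleep/circadian researchers who work with mouse EEG/EMG
(200 Hz, 4-s scoring epochs) and locomotor activity (1-min bins), and covers:

- **Vigilance-state scoring** — a transparent three-rule threshold classifier
  on 4-s epoch features (EMG RMS; SWA 1–4 Hz and θ 7–9.5 Hz band fractions),
  plus sleep-architecture statistics (episode counts/lengths per state and
  phase of day, brief awakenings ≤ 16 s per hour of NREM).
- **State-specific spectra** — Welch periodograms (512-point Hann, 0–50 Hz)
  per 4-s epoch, normalized by each zeitgeber cycle's median total power,
  averaged over the last two cycles; condition comparison with
  cluster-corrected paired t-tests.
- **θ–γ phase-amplitude coupling (PAC)** — mean-vector-length modulation
  index `MI = |Σ a_t e^{iφ_t}|/n`, z-scored against cut-and-swap surrogates
  (PACz), assembled into comodulograms (median PACz over 1-min bins,
  photophase/scotophase separately) and compared between conditions with a
  cluster-mass sign-flip permutation test.
- **Rhythm statistics** — the Sokolove–Bushell χ² periodogram
  (`Qp = K·Σ_h(M_h−M)²/s²` against χ²(P−1)), the fixed-frequency single
  cosinor `y = M + A·cos(ωt + θ)` in its linearized form
  `y = M + β·cos ωt + γ·sin ωt`, and the population-mean (group) cosinor with
  Hotelling-type zero-amplitude and between-condition tests.
- **Two-process sleep homeostasis** — exponential SWA decay
  `SWA(t) = SWA₀·e^(−t/τ) + SWA∞` over accumulated NREM time, the logistic
  SWA buildup at wake→NREM transitions
  `y(t) = min + (max−min)/(1 + 10^((log t₅₀ − log₁₀ t)·Slope))`, and
  extra-sum-of-squares F-tests between conditions.

## Worked example

```python
import numpy as np
from circasleep import (make_schedule, simulate_hypnogram, simulate_eeg_emg,
                        preprocess, compute_epoch_features, score_epochs)
from circasleep.synthetic import SimParams

sched = make_schedule(period_h=24, photofraction=0.5, n_days=1)  # LD12/12
params = SimParams()                       # defaults: kappa=0.6, noise_sd=0.3
hyp = simulate_hypnogram(sched, params, seed=1)
rec = preprocess(simulate_eeg_emg(hyp, sched, params, seed=2))
scored = score_epochs(compute_epoch_features(rec))
print(f"agreement: {np.mean(scored.states == hyp.states[:len(scored)]):.3f}")
print({s: round(float((hyp.states == s).mean()), 3) for s in 'WNR'})
```

prints

```
agreement: 1.000
{'W': 0.539, 'N': 0.375, 'R': 0.085}
```

i.e. on one simulated day at default parameters the threshold scorer
reproduces the generating hypnogram epoch-for-epoch, and the Markov chain
spends ~54% of the day awake, ~38% in NREM and ~8% in REM.  Coupling is
likewise recoverable: at `coupling_kappa=0.8` the wake comodulogram's
maximum lands on the (8 Hz phase, ~38 Hz amplitude) cell with median
PACz ≈ 6, and at `coupling_kappa=0` the matrix stays within |PACz| < 2.

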