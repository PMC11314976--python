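# sleepmat

Sleep-posture detection from a **sparse piezoelectric pressure mat** — a
4 × 8 grid of piezoceramic sensors under the chest, sampled at 100 Hz.
The mat picks up cardiorespiratory micro-vibrations; from one minute of
32-channel voltage the package decides whether the sleeper is **supine,
right-lateral, or left-lateral**. Posture matters clinically: supine
sleep aggravates obstructive sleep apnea, and bedridden patients need
monitored repositioning.

Because clinical mat recordings of this kind are not publicly
deposited, the package ships a first-class **synthetic-data module**
whose signal model mirrors the physics of the device, and every stage
of the method is validated against it.

## The method

For each one-minute sample `U(t)` per channel:

1. **Decomposition.** Two linear-phase FIR band-passes (order 999,
   Dolph-Chebyshev window): respiration `U_res` in 0.1–0.8 Hz, the
   ballistocardiogram (BCG) `U_bcg` in 0.8–15 Hz; the *deviation*
   component is the remainder. On clean signals respiration carries
   ≈ 90 % of the energy, the BCG 5–8 %, the deviation < 3 %.

2. **Artifact screening.** Movement drives the sensors nonlinear.
   Six regularity features per channel — energy entropy of each
   component (windows 400/100/10, steps 40/10/1) and approximate
   entropy ApEn(m = 2, r = 0.2·SD) — feed a 12-hidden-unit logistic
   MLP; a minute is discarded when ≥ 7 of 32 channels are flagged.

3. **Model-based features.** The respiratory component is fit by
   `A_res sin(2π f_res t + φ)`; the BCG by an AM model
   `U_Am (1 + M_bcg cos 2π f_hea t) · cos 2π f_bcg t` with the carrier
   near `5 f_hea` (five IJKL waves per beat). Per-channel driving-force
   intensities come from the total-variation identity of a sinusoid,
   `Σ|ΔU| = 4 A f N Δt`, inverted through the sensor transfer
   `U = (β d33 / C_M) F`. The 4 × 8 intensity grids are bicubically
   upsampled to 16 × 32 **activity maps**; peak trains of the smoothed
   respiration and of the BCG envelope give 2 × 90 and 2 × 180
   amplitude/interval matrices.

4. **Classification.** A four-branch spatiotemporal CNN: two Conv1D
   branches (temporal matrices) and two Conv2D branches (maps), each
   ending in a 32-vector; the 32 × 4 stack is flattened into dense
   layers 64 → 96 → softmax(3). Adam, lr 0.001, batch 48, ≤ 100
   epochs, weight decay 5e-4, L1 1e-5 on the head, dropout 0.5. The
   network is implemented in numpy with explicit backpropagation
   (`sleepmat.nn`) — it is small (~55 k parameters) and trains in
   seconds.

5. **Evaluation.** Subject-grouped 10-fold cross-validation over
   multiple rounds with summed confusion matrices; accuracy, macro
   recall/precision/F1 and one-vs-rest AUC.

## Worked example

```python
import numpy as np
from sleepmat import (SubjectProfile, make_template, synth_minute,
                      BandpassDecomposer, fit_respiration, fit_bcg_am)

profile = SubjectProfile()                   # 15 breaths/min, 72 beats/min
minute = synth_minute(profile, make_template("supine"),
                      movement=False, rng_seed=7)
d = BandpassDecomposer().transform([minute])[0]

w = d.composite_energy / d.composite_energy.sum()
print(f"respiratory energy: {100*(w*d.resp_fraction).sum():.1f}%")

agg = lambda c, e: (np.maximum(e,0)[:,None]*c).sum(0)/np.maximum(e,0).sum()
r = fit_respiration(agg(d.resp, d.resp_energy))
b = fit_bcg_am(agg(d.bcg, d.bcg_energy))
print(f"breathing: {60*r.fres:.1f}/min (R2={r.r_squared:.3f})")
print(f"heart:     {60*b.fhea:.1f}/min (R2={b.r_squared:.3f}), "
      f"carrier/heart = {b.fbcg/b.fhea:.2f}")
```

prints

```
respiratory energy: 91.8%
breathing: 15.0/min (R2=0.992)
heart:     72.0/min (R2=0.948), carrier/heart = 5.00
```

— the decomposition reproduces the ~90 % respiratory energy share, both
rates are recovered, and the BCG carrier sits at five times the heart
rate, as the AM model assumes.

A full synthetic study runs from the command line:

```bash
sleepmat run-all --out run1 --subjects 12 --minutes 120 --seed 1 --epochs 30
sleepmat ablate  --out run1 --seed 1        # temporal / spatial / combined
```

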