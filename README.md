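# swimstates

Latent behavioral-state analysis for larval zebrafish, with a companion
dorsal-raphe calcium-imaging analysis.  The package is aimed at behavioral
pharmacology and systems-neuroscience labs that track single larvae at
high speed in large arenas and want to quantify how treatments (stress,
psychedelics, SSRIs, ketamine) move the animal's swim repertoire — plus a
ground-truthed synthetic-data module so the whole chain is testable without
any recordings.

## What it computes

**Tracking.** From 8-bit video (83 μm/px, 290 Hz): a 100-frame background
model, coarse darkest-pixel detection on the blurred difference image, a
144×144 px patch, and star-centroiding-style subpixel refinement (blur →
invert → median-subtract → 20 %-of-peak threshold → center of mass).  Tail
angle comes from a quadratic fit to seven body points, read out at 1 mm arc
length from the tail base, relative to the body–nostril axis.

**Kinematics.** Velocity-hysteresis bout segmentation; tail half-cycles
referenced to the lateral motion of the head centroid; per bout the beat
frequency, number of tail motions, mean peak angle, inter-bout interval and

```
L/R balance = | (Σ right peak angles − Σ left peak angles)
              / (Σ right peak angles + Σ left peak angles) |
```

(0 = symmetric undulation, 1 = fully one-sided).  A multiplicative model
`distance = k · f^a · n^b · θ^c` fitted to forward swims validates the tail
readout; on synthetic data the exponents recover a ≈ 1, b ≈ 1, c ≈ 0.4.

**States.** Five features per bout (frequency, angle^0.4, count, balance,
interval) are z-scored against a reference dataset and embedded with
2-component FastICA; axes are oriented so IC1 = rapid scooting and IC2 =
turning/escape.  Distribution shifts along single axes are tested with a
kernel-density two-sample permutation test (integrated squared difference
of Gaussian KDEs, Silverman bandwidths).  Four normalized scores summarize
a drug's **stimulatory** effect (spontaneous distance / IC1 shift relative
to the control spont→OMR contrast) and **anxiolytic** effect (reversal of
the stress-induced distance / IC2 shift; full reversal = −1).

**Neural.** ΔF/F = raw / rolling-30th-percentile baseline (2-min window);
per-trial t-test classification of spontaneous-active vs OMR-active
neurons; rank-2 NMF of pooled trial-averaged activity
`V_{i,t} = Σ_n W_{i,n} S_{n,t}`, trajectories normalized by |V|.

## Worked example

```python
import numpy as np
from swimstates import synthetic, kinematics, states

config = synthetic.SessionConfig(session_duration_s=240.0, seed=10)
pose, truth = synthetic.simulate_session(config, synthetic.condition("control"))
bouts = kinematics.analyze_session(pose, config)
qc = kinematics.session_qc(bouts, config)
print(len(bouts), qc.passed, round(qc.rate_per_min, 1))

X, idx = states.build_features(bouts)
norm, model = states.fit_embedding(X, seed=0)
emb = states.project(X, norm, model)
ep = bouts["epoch"].to_numpy()[idx]
print(round(emb[ep == "omr", 0].mean() - emb[ep == "spont", 0].mean(), 2))
```

prints

```
204 True 61.5
0.64
```

— 204 bouts detected (one per generated bout), the session passes the
≥50-OMR-bout QC rule at 61.5 swims/min, and OMR-epoch bouts sit 0.64 units
to the right of spontaneous bouts along IC1 (rapid scooting), as they
should.

The numbered drivers under `analysis/` run the full study on synthetic
cohorts and write their tables to `results/`:

```
python analysis/01_simulate_cohorts.py      # 4 conditions x 6 fish
python analysis/02_localization_benchmark.py
python analysis/03_distance_model.py
python analysis/04_state_embedding.py
python analysis/05_raphe_dynamics.py
```

Representative output: localization error 10.1 μm at peak-SNR 10;
distance-model exponents a=1.006, b=1.015, c=0.395 (r=0.994) on
known-exponent bouts; stimulatory (distance) +0.88 ± 0.06 and anxiolytic
(distance) −1.05 ± 0.11 for the psilocybin-like condition; and a smaller
spontaneous-epoch excursion of the serotonergic-like NMF component after
the drug (0.017 vs 0.033).

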