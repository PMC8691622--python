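# gammasf

Analysis pipeline for **multiple narrowband gamma rhythms in visual-cortex
recordings**: decompose stimulus-driven LFP power spectra into a 1/f
baseline plus three spatial-frequency (SF)–tuned gamma components, quantify
each component's SF tuning, localize components across cortical depth, and
decode object edge vs surface from gamma power. A synthetic-data generator
with known ground truth makes every stage testable without animal data.

Intended users: electrophysiologists and computational neuroscientists
working with multi-trial LFP + spiking data recorded under parametric
visual stimulation (drifting gratings at multiple SFs, plus blank and
edge/surface conditions).

## The model

The trial-averaged power spectrum at one site, as a function of stimulus
spatial frequency SF (cycles/degree) and oscillatory frequency f (Hz), is

```
Power(SF, f) = Baseline(f) + Σ_{i∈{LG,MG,HG}} W_i(SF) · exp(−(f − μ_i(SF))² / 2σ_i²)

Baseline(f)  = k / (f^a + b) + c
μ_i(SF)      = K_{0,i} + K_i · SF^{n_i} / (SF^{n_i} + SF_0^{n_i})      (Naka–Rushton)
W_i(SF)      = A_{1,i} e^{−SF²/2σ_{1,i}²} − A_{2,i} e^{−SF²/2σ_{2,i}²}  (difference of Gaussians, ⌊·⌋₀)
```

with the three components confined to band windows LG 25–45 Hz, MG
45–65 Hz, HG 65–100 Hz. Fitting is bounded nonlinear least squares with
seeded multi-start. A component is counted present when its SNR — peak
fitted weight over SF divided by the mean blank-condition power in its
band — is strictly greater than 3.

Around the core decomposition the package provides multitaper spectral
estimation (Slepian tapers, NW = 3, 5 tapers, 300–2000 ms window),
field–field and spike–field coherence with a within-condition trial-shuffle
control, Hilbert-phase spike locking profiles, relative-depth (ReD) laminar
alignment with a session-resampling bootstrap, and an L1-regularized
logistic edge/surface decoder.

## Worked example

```python
import numpy as np
from gammasf import synthetic as syn, spectral as sp, model as gm, tuning as tun

gt = syn.make_ground_truth("three_gamma_default", seed=1)
rec = syn.simulate_recording(gt, n_trials=30, n_blank=30, seed=0)   # 10 SFs
grid = sp.spectrum_grid(rec)                                        # multitaper
fit = gm.fit_model(grid, seed=0, restarts=10)
print(f"gof={fit.gof:.4f} n_components={fit.n_components}")
for lab in gm.COMPONENT_LABELS:
    curve = tun.component_tuning(fit.params, lab, grid.sfs)
    cut = tun.cutoff_sf(curve)
    print(f"{lab}: cutoff={cut.sf:.3f} cpd selectivity={tun.sf_selectivity(curve):.3f}")
```

prints (to two-ish decimals, seed-dependent):

```
gof=0.9926 n_components=3
LG: cutoff=0.667 cpd selectivity=0.787
MG: cutoff=0.328 cpd selectivity=0.585
HG: cutoff=0.090 cpd selectivity=0.000
```

`gof` is the variance-explained goodness of fit of the 2-D decomposition
(1 = perfect); all three gamma components clear the SNR > 3 criterion; and
the tuning metrics show the characteristic ordering — LG prefers high SF
(large cutoff, high selectivity), HG is low-pass (cutoff ≈ 0.09 cpd,
selectivity ≈ 0), MG is intermediate.

The same pipeline is scriptable from a shell:

```
gammasf simulate --preset three_gamma_default --seed 1 --out run/
gammasf spectrum --recording run/recording.h5 --out run/
gammasf fit --spectrum-dir run/ --out run/
gammasf tuning --fit-json run/fit.json --spectrum-dir run/ --out run/
gammasf decode --features gamma --lambda 0.1 --out run/
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on synthetic data — spectral
decomposition and component counting, tuning metrics, spike–field phase
locking, laminar peak localization with the bootstrap comparison, and the
gamma-vs-MUA edge/surface decoders — logging each stage's summary to
stderr and writing the result object to `--out`.
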