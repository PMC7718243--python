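# qmtcest

Quantitative analysis of saturation-transfer MRI for preclinical tumour
imaging: two-pool magnetization-transfer (MT) model fitting with a
super-Lorentzian semisolid lineshape, WASSR/inversion-recovery relaxometry,
isolation of CEST and rNOE contributions through the extrapolated MT
reference (MTR_REX / AREX), ICA + Gaussian-mixture intratumoural
segmentation, and a digital tumour-phantom generator that forward-simulates
the whole acquisition so every stage can be validated end to end.

## Who this is for

Continuous-wave saturation-transfer (Z-spectrum) studies probe tissue
through three exchange pathways: semisolid MT (membranes, collagen),
CEST from labile solute protons (amide at 3.5 ppm, guanidinium at 2.0 ppm)
and the relayed NOE of aliphatic protons (−3.3 ppm). Separating them
per voxel requires a model-based pipeline: relaxometry, B0/drift
conditioning, a quantitative MT fit, and an MT-only reference spectrum from
which the exchange-mediated contributions are isolated. This package
implements that pipeline for 7 T prostate-xenograft protocols (22Rv1 and
DU145 cell lines) and, because such animal data are rarely deposited,
ships a phantom generator that reproduces the acquisition — Z-spectra at
five saturation amplitudes with interleaved 667-ppm reference frames,
WASSR, a five-TI inversion-recovery series, scanner drift, noise and a
smooth B0 offset field — from voxel-wise ground-truth parameters.

## The models

**Direct saturation** (WASSR T2 mapping) — steady-state single-pool Bloch:

    Z(Δω) = R1 (R2² + Δω²) / ( R1 (R2² + Δω²) + ω1² R2 ),   ω1 = γB1

**Two-pool MT** — free water F exchanging with a semisolid pool at rate
R_MT (MT→F), with saturation rates R_rf,F = ω1²T2,F/(1+(Δω T2,F)²) and
R_rf,MT = π ω1² g(Δ), where g is the super-Lorentzian lineshape of the
semisolid pool:

    Z = [R1,F·R1,MT + R1,F·R_rf,MT + R1,F·R_MT + R1,MT·R_MT·M0,MT] /
        [(R1,F + R_rf,F + R_MT·M0,MT)(R1,MT + R_rf,MT + R_MT) − R_MT²·M0,MT]

The four free parameters are T2,F, R_MT, M0,MT, T2,MT; R_MT and M0,MT are
coupled, so their product (the "MT effect") is the robust scalar. R1,F is
constrained so the slow longitudinal eigenvalue equals the observed
1/T1,obs from inversion recovery.

**CEST/rNOE isolation** — the fitted MT model evaluated at low B1 is the
exchange-free reference Z_EMR, and

    MTR_REX = 1/Z_lab − 1/Z_EMR,      AREX = MTR_REX / T1   [Hz]

**Segmentation** — normalized T1/T2 maps plus the high-B1 Z-images form an
observation matrix; FastICA reduces it to three components, sorted by
normalized mutual information against the mean image and weighted per
tumour type; a 5-component full-covariance Gaussian mixture then yields the
five tissue classes (active tumour, necrosis/apoptosis, muscle,
muscle/connective, blood/edema) through fixed assignment rules.

## Worked example

```python
import numpy as np
from qmtcest import MTParams, two_pool_z, fit_two_pool
from qmtcest.phantom import high_b1_offsets

# forward-simulate noiseless Z-spectra at the 22Rv1 tumour group means
truth = MTParams.from_mt_effect(t2_f_ms=47.0, mt_effect_hz=1.8,
                                t2_mt_us=7.8)
t1_obs = 2200.0
wassr = np.round(np.arange(-1.0, 1.001, 0.1), 10)
high = high_b1_offsets()          # ±log-spaced 3-300 ppm
spectra = {b1: (offs, two_pool_z(offs, b1, truth, t1_obs))
           for b1, offs in [(0.1, wassr), (3.0, high), (6.0, high)]}

res = fit_two_pool(spectra, t1_obs, seed=0)
print(res.summary())
```

prints

```
Two-pool MT model fit
=====================
         param     estimate      std err
       t2_f_ms           47    3.107e-14
       r_mt_hz           25    4.759e-14
         m0_mt        0.072    5.584e-17
      t2_mt_us          7.8    2.902e-15
mt_effect_hz (R_MT*M0,MT): 1.8
r1_f_hz (constrained): 0.416111
t1_obs_ms (fixed): 2200.0
n_obs: 81
resid_norm: 2.5912942535768196e-15
converged: True
boundary_pinned: False
```

i.e. the fit recovers the generating free-pool T2 (47 ms), MT effect
(1.8 Hz) and semisolid T2 (7.8 µs) exactly from the 81 noiseless spectral
points; with measurement noise the `std err` column carries the asymptotic
uncertainties.

A full synthetic study runs from the shell:

```bash
qmtcest run-all --type 22Rv1 --out run/ --seed 0
```

which simulates a 64×64 phantom, preprocesses it (drift correction from
the interleaved references, WASSR B0 mapping, re-centring, mask erosion,
B0-outlier exclusion), fits T1/T2 maps, fits the two-pool model per ROI,
writes AREX/MTR_REX maps at 3.5/2.0/−3.3 ppm, segments the slice, and
emits per-region summary tables with Student's t comparisons.

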