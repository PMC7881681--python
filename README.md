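# mollifit

Cardiac T1 mapping from MOLLI inversion-time image series: pixel-wise
inversion-recovery curve fitting, Look-Locker correction, and extracellular
volume fraction (ECV) maps — with a synthetic cardiac phantom so every stage
is testable without clinical data.

## Who this is for

Researchers in quantitative cardiac MRI who have a co-registered stack of
magnitude TI images (clinically: a DICOM series carrying `InversionTime`)
and want per-pixel myocardial T1 and ECV, plus the evaluation machinery
(ROI means, Bland–Altman agreement) used to compare T1 estimation methods.

## The model

Each pixel's signal across inversion times follows the three-parameter
relaxation curve

    S(t) = a (1 − e^(−b t)) + c

where `c` is the (negative, post-inversion) signal at t = 0, `a + c` the
recovery plateau, and `b = 1/T1*` the apparent relaxation rate under the
repeated MOLLI readouts. The true T1 follows from the Look-Locker correction

    T1 = T1* (a/(a + c) − 1).

The objective is the sum of squared residuals over the N samples (N = 8 for
the pre-contrast 5(3)3 scheme, 9 for the post-contrast 4(1)3(1)2 scheme).
Two estimators are provided:

* **LM** — Levenberg–Marquardt from a fixed start (default `(350, 0.001,
  −150)` pre-contrast, `(350, 0.005, −150)` post-contrast), re-run while
  incrementally flipping the polarity of the earliest-TI magnitude samples;
  the flip count with the smallest residual wins.
* **RD** — reduced-dimension nonlinear least squares: for fixed `b` the
  model is linear in `(a, c)` with a closed-form solution, so the fit
  collapses to a 1-D search over `b` (dense log-spaced grid plus bounded
  refinement). Polarity is restored from three candidate flip counts
  bracketing the minimum-magnitude sample, which is robust where
  near-coincident TIs make the minimum itself noise-sensitive.

ECV is computed pixel-wise from co-registered pre/post maps as
`ECV = (1 − Hct) · ΔR1_tissue / ΔR1_blood` with `ΔR1 = 1/T1_post − 1/T1_pre`.

## Worked example

```python
import numpy as np
from mollifit import InversionRecoveryT1, RelaxationParams, generate_molli_tis

tis = generate_molli_tis("5(3)3", rr_ms=1000, ti_bases=(120, 200))
truth = RelaxationParams(a=300, b=1/800, c=-150)        # ideal inversion: T1 = 800 ms
model = InversionRecoveryT1(np.abs(truth.a*(1-np.exp(-truth.b*tis)) + truth.c), tis)
res = model.fit(method="rd")
print(res.summary())
```

prints

```
Inversion-Recovery T1 Fit Results
==============================================
Method:            RD
No. observations:  8
Converged:         True
Flip count:        2
RSS:               1.37704e-12
----------------------------------------------
 param       estimate      std err     unit
     a            300     5.82e-07   signal
     b        0.00125    7.474e-12     1/ms
     c           -150    5.906e-07   signal
----------------------------------------------
T1* (apparent):    800.00 ms
T1  (corrected):   800.00 ms  (se 2.63e-06)
==============================================
```

The flip count 2 says the two earliest TIs (120 and 200 ms) lie before the
zero crossing at `T1* ln 2 ≈ 555 ms` and had their magnitude-scale polarity
restored to negative; with an ideal inversion (`a = −2c`) the Look-Locker
factor is exactly 1, so T1 equals the apparent T1*.

Whole images go through the map layer and CLI:

```bash
mollifit phantom --out demo --rows 64 --cols 64 --noise-sigma 7 --seed 1
mollifit fit --input demo/dicom --out demo/t1 --method rd --threshold 60 --workers 4
mollifit inspect --input demo/dicom --row 32 --col 32 --out demo/px.png
mollifit agree --map-a demo/t1/t1_map.nii.gz --map-b other/t1_map.nii.gz
```

`fit` writes the T1 map as NIfTI (invalid pixels NaN), CSV and a PNG
preview, plus a JSON sidecar with everything needed to reproduce the run.

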