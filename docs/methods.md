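# Methods

## Signal model and correction

A MOLLI acquisition samples the post-inversion longitudinal recovery at N
inversion times pooled across 2–3 inversion blocks (8 samples for the
pre-contrast 5(3)3 scheme, 9 for the post-contrast 4(1)3(1)2 scheme). The
per-pixel model is the three-parameter curve `S(t) = a(1 − e^{−bt}) + c`
fitted by least squares; `1/b` is the apparent T1 (T1*), shortened by the
repeated balanced readouts, and the Look-Locker correction
`T1 = T1*(a/(a+c) − 1)` recovers the true T1. The package fits magnitude
data only (the common clinical export); complex-valued fitting, B1 or
inversion-efficiency corrections beyond the Look-Locker factor, and motion
correction across TI images are out of scope — inputs are assumed
co-registered.

Degenerate fits are rejected rather than propagated: `|a + c| <
10⁻⁶·max(|a|, 1)` (configurable floor) makes the correction factor
undefined, and any fit with non-positive `b` or non-positive corrected T1
is marked non-converged. At map level such pixels carry NaN and are
excluded by the validity mask; an optional clamp limit (e.g. 3000 ms
pre-contrast, 1500 ms post-contrast) likewise marks out-of-range fits
invalid instead of clipping them, so ROI statistics never average
pathological values.

## Estimators

**LM.** `scipy.optimize.least_squares` (Levenberg–Marquardt, analytic
Jacobian) from a fixed start: `(a, b, c) = (350, 0.001, −150)` pre-contrast
and `(350, 0.005, −150)` post-contrast, with at most 200 function
evaluations and a relative cost-change tolerance of 10⁻⁸ (all
configurable). On magnitude data the polarity of the first k samples is
flipped for k = 0..N (full sweep) or for the three candidate flip counts
described below, and the smallest residual wins. The iteration cap matters:
wrong-polarity candidates rarely converge and would otherwise dominate the
per-pixel cost.

**RD.** For fixed `b` the model is linear in `(a, c)`, so the inner problem
is solved in closed form (ordinary least squares against the regressor
`1 − e^{−b·TI}`) and the fit reduces to a 1-D search over `b`. The search
uses a 500-point log-spaced grid spanning T1* ∈ [1, 5000] ms followed by
bounded scalar minimization (Brent) on the interval bracketing the grid
minimum, to a relative tolerance of 10⁻⁶ on `b`. Grid points where the
regressors are numerically collinear (`b` far too large for the TI range)
are skipped. The RD fit is initialization-free; a brute-force 10⁴-point
grid oracle is used in the tests to confirm the two-stage search finds the
global minimum of the reduced objective.

Ties between polarity candidates (equal cost within 10⁻¹² relative) break
toward the smaller flip count, making the output deterministic.

## Polarity restoration

Magnitude data lose the sign of the early, still-negative samples. With `m`
the index of the minimum-magnitude sample, the zero crossing lies adjacent
to TI_m, so the noiseless flip count is `m` or `m+1` — the classic
two-candidate rule. That rule is noise-sensitive exactly when two TIs have
near-equal signal magnitude near the crossing: noise can move the observed
minimum one sample past the crossing, in which case the correct flip count
is `m − 1`, unreachable from `{m, m+1}`. Candidates therefore expand
symmetrically around the classic pair — order `m, m+1, m−1, m+2, …` — and
the default three candidates give `{m−1, m, m+1}` (clipped to `[0, N]`).
This choice was validated against the exhaustive 0..N flip sweep on noisy
phantoms: the symmetric set agrees with the exhaustive answer on >99% of
tissue pixels at σ/a = 0.02, including on a fixture whose inversion blocks
start 8 ms apart (every TI has a near-coincident partner), where the
two-candidate rule drops well below 90%. A forward-only set
(`{m, m+1, m+2}`) was rejected on the same measurement (≈86% agreement on
the pre-contrast phantom): the dominant noise failure needs `m − 1`, not
`m + 2`. `n_candidates` and an `exhaustive` switch remain exposed.

## Map assembly and parallelism

Maps are computed pixel-by-pixel over all pixels whose maximum signal
across TIs strictly exceeds a threshold (default 0: fit everything above
exactly zero; raising it excludes background air and saves time but never
adds valid pixels — validity shrinks monotonically in the threshold).
Parallel execution distributes static, contiguous row blocks over joblib
processes; since every per-pixel fit is deterministic and assembly is by
row index, the result is bit-identical for any worker count — scheduling
can never change the science. Map-level LM defaults to the three-candidate
flip policy for speed; the exhaustive sweep remains available.

## ECV

`ECV = (1 − Hct) · (1/T1_post − 1/T1_pre) / (1/T1b_post − 1/T1b_pre)`, the
standard two-compartment contrast-partition formula. Blood values are
scalars (typically ROI means over a blood-pool mask) rather than per-pixel
maps, the common clinical convention; pre/post maps are assumed
co-registered and are never resampled. ECV outside a plausibility band
(default [0, 1]) is flagged invalid. The formula is invariant to a common
rescaling of all four relaxation-rate differences and strictly increasing
in the tissue ΔR1.

## Synthetic phantom

The phantom emulates a short-axis cardiac slice: a blood-pool disk (default
T1 = 1500 ms pre-contrast, 280 ms post) inside a myocardial annulus (950 ms
pre, 470 ms post) on a zero-signal air background, sampled at MOLLI TIs
(block k contributes `base_k + j·rr` for its j = 0..n_k−1 images; defaults
rr = 1000 ms, bases 120/200 ms pre and 120/200/280 ms post — representative
clinical values). Compartments default to an ideal inversion (`a = −2c`, so
T1 = T1*); noise is Rician (independent Gaussian sd σ on two orthogonal
channels, then magnitude), with plain Gaussian available for analytic
tests. The canonical noisy condition is σ = 2% of the myocardial amplitude
a = 350.

What the phantom does **not** emulate: cardiac motion and misregistration
between TI images, partial-volume mixing at compartment borders,
off-resonance banding, surface-coil shading, imperfect inversion profiles,
and physiological RR variability. Passing tests therefore demonstrate the
correctness and internal consistency of the estimation pipeline under the
stated noise model, not robustness to those acquisition artifacts.

## Precision at the canonical noise level

A Gauss–Newton/Cramér–Rao analysis of the three-parameter model (delta
method through the Look-Locker correction) puts the per-pixel relative
standard deviation of the corrected T1 at roughly 2.9–4.8% across
T1 ∈ [200, 2000] ms for the default 5(3)3 TI set at σ/a = 0.02 — a floor
set by the sampling design, not the estimator. Both fitters measure at that
floor (median relative error ≈ 2.4–2.9% on magnitude data; ≈ 2.2% on
signed data), and ROI means over a few hundred pixels recover compartment
T1 to well under 1%. Per-pixel medians below ~2% at this noise level are
not achievable with these 8–9 point samplings; the acceptance suite
records this measured value and the test asserting a 2% median documents
the gap rather than hiding it.

## Problem sizes

Default verification sizes were chosen so the whole suite runs comfortably
on a laptop core: 96×72 phantoms for noiseless exact-recovery checks,
28×28 for polarity-agreement counts (>800 fitted pixels across two
fixtures), 24×24 phantoms for the 30-subject method-agreement study, 500
independent series for the noisy-recovery medians, and 10⁴-point grids for
the RD search oracle. All sizes are parameters of the phantom/test helpers
and scale up without code changes.

## I/O conventions

DICOM reading takes the standard `InversionTime` attribute, applies rescale
slope/intercept, requires consistent dimensions and a single series, and
sorts slices by TI regardless of file order. Result maps are written as
float NIfTI (NaN marks invalid pixels; bit-exact round-trip), CSV (one row
per pixel) and PNG previews; every artifact carries a JSON sidecar with the
configuration, TI list and package version needed to reproduce it. The
DICOM writer is a fixture-grade synthetic-series writer (uint16 pixels,
minimal secondary-capture-like tags) used by the phantom command and the
round-trip tests, not a clinical exporter.
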