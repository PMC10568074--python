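# Methods

## Signal model

The STAIR cycle is modelled as a periodic sequence: adiabatic inversion
(longitudinal magnetization scaled by the inversion efficiency Q), free T1
recovery for TI, a 90° excitation that zeroes the longitudinal
magnetization, readout with T2\* decay, and recovery for the remaining
TR − TI. Its steady state has the closed form

S = M0 (1 − Q e^(−TR/T1) − (1 − Q) e^(−TI/T1)) e^(−TE/T2\*).

Assumptions: exactly 90° excitation (other flip angles are rejected rather
than approximated), no B0/B1 inhomogeneity, no magnetization transfer or
exchange between pools. Signals are kept *signed* so that null crossings
are testable; magnitude enters only through the phantom's Rician noise
stage. An explicit cycle-recursion simulator (`steady_state_oracle`)
provides an independent fixed-point check of the closed form; because the
excitation erases longitudinal memory each cycle, the recursion converges
in one period, and the suite verifies agreement to 1e−8 over random
parameter draws.

The proton-density reference is modelled as S = M0 e^(−TE/T2\*): at a 5°
flip angle and TR ≫ T2\* the acquisition is proton-density weighted, and
TR/flip-angle dependence is absorbed into the arbitrary units of M0 (it
cancels in no quantity of interest; only the STAIR/PD ratio matters).

All times are milliseconds everywhere; the config loader warns on
seconds-scale repetition times (TR > 10 000 ms) because mixed units are
the most likely silent corruption.

## Inversion-time optimisation

A single TI nulls a single T1, but the long-T1 band spans 600–2000 ms. The
optimiser minimises the mean squared residual 1 + e^(−TR/T1) − 2 e^(−TI/T1)
(per unit M0, pre-TE, Q = −1) over a uniform 141-point T1 grid, via a 1 ms
scan bracketing followed by bounded scalar minimisation to 0.01 ms. At
TR = 250 ms this yields TI = 116.73 ms → 117 ms on the protocol card, with
worst-case residual 1.3 % of M0. A minimax objective is available
(`objective="minimax"`); it lands ≈ 2 ms lower, where the short-T1-edge
residual balances the interior minimum. The least-squares optimum does not
minimise the worst case — the single-T1 null of the 600 ms edge actually
has a *smaller* worst-case residual (≈ 1.0 %) — but it minimises the
band-average leakage power, which is what governs the pooled bias of the
aMWF estimate.

## Adiabatic pulse Bloch simulation

The inversion pulse is a hyperbolic-secant (HS1) adiabatic full passage of
duration 8.64 ms: envelope A(τ) = B1_peak · sech(βτ), sweep
f(τ) = −(μβ/πT_p) · tanh(βτ), τ ∈ [−1, 1], with β = 5, μ = 4.9, 2048
samples. The pulse's peak amplitude is not dictated by the protocol, so it
is calibrated once: the smallest value on a 50 Hz grid for which a
long-relaxation pool (T1 = 1000 ms, T2 = 2000 ms) is inverted to
Q ≤ −0.98. This lands at 700 Hz (stored in `data/defaults.yaml`), safely
on the adiabatic plateau (raising B1 by 25 % changes the long-T2 Q by
< 0.01).

Integration is operator splitting per RF sample: a hard rotation about the
effective field (RF along x, instantaneous offset along z, in the
frequency-modulated frame) followed by exponential T1/T2 decay over the
same 4.2 µs interval. A fixed-step RK4 integrator of the full Bloch
equations serves as the independent cross-check (agreement to < 5e−4 in
Mz); halving the step (doubling the sample count) changes Q by < 1e−4.
Only on-resonance spins are simulated; no B0/B1 maps, slice-selection
gradients or SAR modelling.

With the calibrated pulse, the myelin-water pool (T1 = 220 ms,
T2 = 10 ms) reaches Q = −0.84: the passage spends milliseconds with the
magnetization partly transverse, and a 10 ms T2 destroys part of it.
Because the pulse's amplitude, bandwidth and exact shape are free design
parameters, the achievable Q for short-T2 species varies by roughly ±0.1
across reasonable calibrations; the quantification default remains
Q_MW = −0.75, and both the constant and the pulse parameters are exposed
in the config.

## Digital phantom

Geometry: 64×64×15 voxels of 1.72×1.72×5 mm (a desk-scale stand-in for a
128×128×15 acquisition), an ellipsoidal brain with a cortical GM shell, a
WM core, a central CSF ellipsoid, eight procedurally placed WM sub-ROIs
(≈ 50 voxels each, mirroring the eight white-matter regions quantified per
subject) and, for patients, 9 non-overlapping WM lesions per subject
(rejection-sampled, seeded; 63 lesions per 7-patient cohort, emulating the
66 quantified in vivo).

Tissue table (aMWF / long-pool T1): WM 9.9 % / 850 ms (healthy) or
8.5 % / 900 ms (patient NAWM), lesion 3.6 % / 1100 ms, GM 3 % / 1500 ms,
CSF 0 % / 4000 ms; relative proton densities 0.7 / 0.8 / 1.0
(WM / GM / CSF). White-matter values sit in the reported 750–1000 ms T1
band; GM, CSF and lesion long-pool values are editorial defaults exposed
in config. Between-subject variability: each subject's class aMWF is
jittered with SD 1.3 pp (NWM, lesion) / 1.2 pp (NAWM), matching the
reported group SDs.

Forward modes: `model_matched` (the acquisition equals the estimator's
model exactly — used for unbiased-recovery tests) and `two_pool` (both
compartments contribute to both images, so incompletely suppressed long-T1
signal leaks into the STAIR image and biases the apparent MWF upward; the
bias shrinks as the long-pool T1 approaches the suppression null near
980 ms).

Noise: per excitation, independent complex Gaussian noise with SD
`noise_sigma` × (WM PD signal) per channel; the NEX excitations (30 STAIR,
10 PD) are averaged in the complex domain before the magnitude — as
scanner NEX averaging does — which keeps the Rician floor at σ/√NEX
(magnitude-domain averaging is available behind a flag). The default
`noise_sigma = 0.01` (single-excitation PD-image SNR ≈ 100 in WM) was
chosen as representative of a multi-shot EPI brain protocol at 3 T. At
this level the post-averaging STAIR-image SNR is ≈ 7 in WM and ≈ 3 in
lesions, leaving a predictable Rician magnitude bias of ≈ +0.1 pp (WM)
to ≈ +0.3 pp (lesions) in recovered aMWF.

What the phantom does **not** emulate: EPI k-space artefacts (ghosting,
distortion, eddy currents), coil sensitivities, motion, partial volume at
tissue interfaces beyond voxelisation, B0/B1 fields, and anatomical
realism. Passing recovery tests therefore demonstrates correctness of the
estimator under its own noise and signal model, not robustness to scanner
artefacts.

## Quantification

aMWF = k · S_STAIR / S_PD with k from the fixed constants (≈ 7.44 for the
default protocol). Voxels whose PD signal falls below 10 % of the robust
(99th-percentile) maximum are masked out rather than divided; the largest
connected component is kept. Negative ratios (noise-dominated voxels) are
clipped to 0 and values above 1 to 1, with clip counts recorded on the
map. STAIR and PD volumes are assumed co-registered (acquired
back-to-back); no registration is attempted.

## Statistics

Group comparison pools per-ROI means (8 WM ROIs × 7 subjects per WM group)
and per-lesion means as independent observations — deliberately mirroring
the study's analysis; no mixed-effects correction for within-subject
correlation is applied, so p-values are anti-conservative in the same way.
The report prints its n explicitly. Components:

- KS normality with the Lilliefors correction by default (parameters are
  estimated from the sample); the plain KS variant is a flag.
- Classical one-way ANOVA (between/within decomposition).
- Games–Howell post hoc: Welch standard errors and Welch–Satterthwaite
  df per pair, adjusted p from scipy's studentized-range distribution
  (q = |t|·√2, k groups). It converges to Tukey HSD for large balanced
  equal-variance groups; at small n the Welch df keeps it valid under
  variance heterogeneity. Family-wise type-I error is verified at
  0.05 ± 0.01 under the global null (n = 7 per group).
- 95 % CIs of group means are t-based.

## Problem sizes and determinism

The cohort recovery estimates pool replicate cohort simulations (18 in the
test suite, 24 in the acceptance script) so that the between-subject
sampling SE of a pooled group mean (≈ 0.5 pp for a single 7-subject
cohort) drops to ≈ 0.1 pp; per-cohort conditions (7 + 7 subjects, jitter
SDs, noise level, NEX) are unchanged by replication. All randomness flows
from explicit seeds through numpy `SeedSequence` spawning, so identical
seeds give identical volumes across platforms. Monte Carlo calibration
checks (type-I error, CI coverage) use 10⁴ vectorised simulations.

## Known limitations

- Q_MW from the Bloch module depends on the calibrated pulse amplitude and
  shape parameters, which the protocol does not pin down; the
  quantification constant is fixed at −0.75 independently of the simulated
  value.
- The aMWF is *apparent*: residual long-T1 leakage (two-pool mode shows
  ≈ +2 pp at WM-like T1), the fixed constants, and the Rician floor all
  bias it; the toolkit quantifies these biases but does not correct them.
- The PD model ignores T1 weighting of the reference scan; in vivo a 5°
  flip at TR = 250 ms retains mild T1 weighting that folds into the
  "apparent" scaling.
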