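# Methods

## Signal model

ΔM is modeled with the single-compartment continuous-labeling solution
(piecewise in time since labeling onset t = PLD + τ: zero before bolus
arrival, exponential approach during delivery, T1 decay after the bolus
ends), with delivery rate 2·α·M0·(f/6000)·e^{−Δt/T1b}. The closed form is
verified in the tests against forward-Euler integration of the underlying
mass balance dΔM/dt = delivery(t) − ΔM/T1 at a 0.1 ms step; agreement is
well inside 0.1% over f ∈ [10, 500] ml/100 g/min, PLD ∈ [200, 3000] ms,
Δt ∈ [0, 1500] ms, T1 ∈ [600, 2000] ms.

The f/6000 factor is the package's unit convention for converting
perfusion in ml/100 g/min into a per-millisecond delivery rate; it is
applied identically in the simulator and the inverter, so perfusion maps
are in ml/100 g/min end to end and round trips are exact. A consequence of
this convention is that simulated ΔM amplitudes are large relative to M0;
noise levels are therefore specified relative to ΔM (see noise model).

Kinetic constants default to the consensus 3 T pCASL values — T1b = 1650
ms, α = 0.85, λ = 0.9 ml/g, τ = 1500 ms, Δt = 0 ms — and are carried in a
single `KineticConstants` object shared by simulation and quantification,
which is what makes the noise-free round trip exact by construction rather
than approximately. All are overridable; λ enters only the optional
one-compartment shortcut ("whitepaper") mode, which ignores the tissue T1
map: f = 6000·λ·(ΔM/M0)·e^{PLD/T1b} / (2·α·T1b·(1 − e^{−τ/T1b})).

### Subtraction convention

ΔM defaults to control − label (perfusion-positive). Acquisitions whose
selective/non-selective naming implies the opposite order can flip the sign
via `subtraction_order="label-control"`; nothing downstream changes except
the sign.

## Quantification chain

1. **Pair differences.** Per nominal PLD, ΔM_i = control_i − label_i.
2. **Motion rejection.** Each pair is scored by the mean absolute
   deviation of its ΔM image from the voxelwise median ΔM image; scores
   are standardized by median/MAD (scale 1.4826) and pairs with robust
   z > 3 (default) are dropped. At least one pair always survives. The
   statistic is deliberately relative: a session in which *every* pair is
   equally corrupted has no outlier and nothing is dropped. Measured
   operating characteristics on simulated breath-hold failures (rigid
   in-plane shifts of ≥ 2 voxels in 10–30% of pairs, cortical ΔM SNR 20):
   detection sensitivity ≥ 90%, false rejection ≤ 5% — recomputed by the
   acceptance script.
3. **Averaging and normalization.** Surviving ΔM images are averaged and
   divided voxelwise by the base M0 image, floored at `m0_floor` (default
   1e-6 signal units); sub-floor voxels are marked invalid rather than
   producing infinities.
4. **T1 mapping.** S(TI) = A(1 − 2e^{−TI/T1}) is fitted per voxel on
   signed IR data. The model is conditionally linear in A, so the fit is a
   1-D profiled search over T1: a 20-node log-spaced grid on [200, 3000] ms
   brackets the optimum, then a bounded scalar minimization (xatol 1e-6 ms)
   polishes it and A is recovered in closed form. `fit_ok` is false where
   the relative residual exceeds 5%, T1 lands on a bound, A ≤ 0, or the
   voxel is all-zero. Magnitude-mode data must have polarity restored
   (negate samples before the signal minimum) before fitting; the
   two-parameter model is not identifiable on unsigned data.
5. **Inversion.** f = (ΔM/M0) / ΔM(f=1, M0=1) per voxel, per slice at the
   effective PLD = nominal PLD + acquisition position × slice readout time
   (default 45 ms; an ordering table maps spatial slice to acquisition
   position). Non-positive or non-finite ΔM yields f = 0 and
   `valid = False` (configurable to NaN) — perfusion is non-negative and
   sign-cancellation artifacts must not leak into ROI means. Estimates
   above `f_max` = 5000 are clipped and invalidated.

### Multi-PLD mode

An optional joint nonlinear least-squares fit of (f, Δt) across all
effective PLDs, Δt bounded to [0, min PLD + τ], three Δt starts with an
early exit once a start explains the data exactly. Identifiability caveat:
when every readout falls after the end of bolus delivery (effective
PLD > Δt for all samples with the whole bolus passed, i.e. t > Δt + τ
everywhere), the model factorizes as C(f, Δt)·e^{−t/T1} and (f, Δt) lie on
an exact ridge — the data cannot distinguish them. Recovery tests therefore
place the true Δt above the shortest PLD; with Δt = 0 data the returned f
still matches the single-PLD inversion because the zero-Δt start is
preferred on ties.

## Phantom and noise model

Phantoms are rasterized geometric primitives (spheres, ellipsoids, shells)
painted in list order, later regions overwriting earlier ones — the default
phantom builds a kidney as a cortical ellipsoid overwritten by a medullary
core, and a tumor overwritten by a necrotic center. Default tissue values
are physiological: cortex 250, medulla 60, solid tumor 300, necrosis 10
ml/100 g/min; T1 1150/1500/1400/1800 ms; M0 100; Δt 0. (Published renal
ASL studies sometimes print much larger map-level RBF values; those
magnitudes are study-specific and are used here only to calibrate the
cohort-table generator, never the phantom.)

Noise is additive Gaussian, independent per image — subtraction of two
Gaussian images keeps the ΔM noise Gaussian and zero-mean, which the
oracle statistics rely on. Rician magnitude bias is not modeled; at the
simulated SNRs the difference is negligible for the questions asked here.
An optional separate noise level for the M0/IR calibration images
(`calib_noise_sd`) reflects that single-shot difference pairs are far
noisier than calibration images; by default every image gets the same sd.
Breath-hold failure is modeled as a rigid in-plane translation of the label
image of randomly chosen pairs (edge voxels replicated) — pairs are
rejected, not realigned, so no registration machinery exists or is needed.

What the phantom does *not* emulate: k-space/EPI artifacts, B0/B1
inhomogeneity, partial-volume mixing at region boundaries, respiratory
waveforms beyond pair-level shifts, or vascular crushing/bolus dispersion.
Passing tests therefore demonstrate the correctness of the processing
chain and the statistics under the stated signal model, not robustness to
every artifact of in-vivo data.

## ROI rules

Cortex, medulla, entire tumor, and the solid part of the tumor avoiding the
necrotic area. Hand-drawn ROIs are replaced by two mechanisms: phantom
truth masks (for validation) and a threshold heuristic for the solid part —
tumor voxels strictly above the 0.25 (default) within-tumor perfusion
quantile, with a homogeneous tumor or quantile 0 keeping every valid tumor
voxel and a threshold that ties the maximum keeping the top ties. The mask
is always a subset of the tumor and shrinks weakly as the quantile grows
(property-tested). The quantile is an explicit stand-in for a manual
reading, not a claim about how any radiologist drew a boundary; it
separates core from rim exactly only when the necrotic fraction and
quantile are compatible, which is why phantom-truth masks remain available.
Region summaries use sample (n−1) SD over valid voxels only and report the
valid fraction so degraded fits stay visible.

## Cohort generator

One row per patient: MVI label, covariates, and per-PLD entire-tumor and
solid-part perfusion drawn from zero-truncated normal distributions.
Solid-part group parameters (MVI+: 536.4±154.8, 2912.5±939.3, 3280.3±901.2;
MVI−: 453.5±87.2, 1043.6±695.8, 1577.6±1085.8 ml/100 g/min at PLD 1/2/3)
and the 12/27 group sizes are the study calibration. Per-group entire-tumor
parameters are not part of that calibration and were derived once from the
pooled entire-tumor means/SDs and the entire-tumor AUCs via the binormal
relation AUC = Φ(d/√2). Covariates: diameter normal (MVI+ 4.7±1.8 cm,
MVI− 3.6±2.1 cm, truncated at 0.5), ill-defined margin Bernoulli (2/3 vs
1/3), shape categorical, ISUP grade shared between groups (the study design
treats grade as non-discriminating). All draws honor the configured seed exactly;
SD = 0 degenerates to the mean.

## Statistics

- **Paired t / Student's t** via scipy; pooled-variance df = n₁+n₂−2 by
  default, Welch by flag. Zero-variance inputs raise — the statistic is
  undefined, and the pipelines surface the condition as an explicit report
  flag rather than a number.
- **ICC(2,1)** (two-way random effects, absolute agreement, single
  measurement) from the ANOVA mean squares:
  (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)); ICC(3,1) by
  flag. Duplicated sessions give exactly 1; constant matrices raise.
  Verified against a brute-force mean-squares oracle (1e-10) and
  cross-checked against pingouin's ICC(A,1).
- **ROC/AUC** over all unique thresholds (positive when score ≥ threshold),
  trapezoidal AUC — equal by construction to the tie-corrected
  concordant-pair probability, asserted against exhaustive pair counting —
  and Youden-J cutoff with smallest-threshold tie-break.
- **Diagnostic indices** from explicit confusion matrices with Wilson 95%
  intervals (stable at proportions of 0 and 1). PPV/NPV are reported as
  not-applicable when no positive/negative calls exist. No attempt is made
  to reverse-engineer any published index quartet; indices are only ever
  computed from stated counts.
- **Logistic regression** by Newton/IRLS (statsmodels backend), intercept
  added unless the design already carries a constant column, convergence
  re-assessed from the score equations (max |X'(y−p)| < 1e-8).
  Quasi-complete separation — standardized slope norm > 15 or a singular
  information matrix — is flagged `converged = False` with a message; the
  estimator stays plain maximum likelihood (no Firth penalty) so reported
  odds ratios are the conventional ones. Verified against an independently
  coded Newton–Raphson optimizer to 1e-6.
- No multiple-testing adjustment is applied anywhere; per-test α = 0.05 is
  reported as-is, matching the study design this mirrors.

## Study pipelines, seeds, problem sizes

A master seed fans out via SHA-256 of (seed | stage | subject | session)
to sub-seeds below 2³¹, so every stage is independently reproducible and
identical configs yield byte-identical reports (manifests record a config
hash and output digests).

The reproducibility study simulates n subjects × 2 sessions on a 20×20×3
phantom grid with 4 pairs/PLD; subjects draw cortical f ~ N(250, 25²) and
medullary f ~ N(60, 6²); acquisition noise is set so a single cortical ΔM
image has SNR 20 (calibration images SNR 100). Because noise is additive
in signal units, the medulla's four-fold smaller ΔM makes it intrinsically
the low-SNR measurement — the cortical vs medullary ICC ordering is a
structural prediction, not a tuned outcome. The MVI study runs on the
default 39-patient cohort. Grids, pair counts and subject numbers are
desk-scale choices that keep the full suite in tens of seconds while
leaving every estimate comfortably inside its tolerance; the acceptance
script states the n it used alongside every number.

## Known limitations

- Single-compartment kinetics: no dispersion, no exchange limitation, no
  partial-volume correction.
- Motion handling is rejection-only and pair-level rigid; slow drifts that
  corrupt every pair equally are invisible to a relative outlier statistic.
- The multi-PLD (f, Δt) fit is ridge-degenerate whenever all samples are
  post-bolus (see above).
- The cohort generator draws covariates independently given the group
  label, so it cannot emulate covariate-covariate correlation structure.
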