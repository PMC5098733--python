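# Methods

`pdtmri` implements a multi-parametric quantitative MRI analysis chain for
small-animal tumor therapy-response studies — the kind of protocol used to
monitor vascular-targeted photodynamic therapy (PDT) of subcutaneous tumors
at 7 T — together with a digital tumor phantom that provides ground truth
for validating every stage. This note records the models, the estimator
choices, the phantom's scope, and the numerical conventions.

## Signal models and estimators

**Flip-angle (B1) correction.** Transmit-field inhomogeneity scales the
nominal flip angle by an unknown per-voxel factor ζ. It is measured with a
180°-signal-null acquisition at three nominal angles (145°, 180°, 215°):
magnitude signal follows S = |a·FA_n + b|, and ζ = −(a/b)·180°. Because the
magnitude hides residual signs, the fit enumerates every sign split
consistent with a single null crossing (at most n−1 for n angles plus the
no-crossing case), solves each by ordinary least squares, and keeps the
lowest SSE; ties are broken toward ζ = 1. Voxels with b = 0 or ζ outside a
plausibility window (default 0.5–1.5) are marked invalid; downstream
consumers fall back to ζ = 1 (no correction) for those voxels.

**T1 (variable flip angle).** Spoiled gradient-echo steady state,
S = M0·sin α·(1−E1)/(1−E1·cos α) with E1 = exp(−TR/T1) and α = ζ·FA_n.
Default protocol: TR = 20 ms, 7 nominal angles 2–20°. The final estimate
comes from bounded nonlinear least squares over (M0, T1) with an analytic
Jacobian, initialized from the classical linearization (S/sin α regressed
on S/tan α). Bounds: T1 ∈ [50, 10000] ms. The nonlinear criterion is
preferred because the linearized form mis-weights noise at low signal;
convergence onto a bound is reported as invalid, never as an estimate.

**T2 (multi-echo).** S = A·exp(−TE/T2) over 7 echo times 0.9–82.6 ms,
bounded NLLS with log-linear initialization, T2 ∈ [1, 2000] ms. No
noise-floor offset term is included; with the phantom's Gaussian noise
option and SNR ≥ 50 the offset-free model is adequate, and adding an offset
is a model change, not a default. A constant series drives T2 to the upper
bound and is flagged invalid.

**ADC (diffusion).** Mono-exponential decay S = S0·exp(−b·ADC) per
diffusion direction (b = 0, 100, 200, 400 s/mm², 3 orthogonal directions);
the per-direction estimate is the log-linear least-squares slope and the
orientation-invariant ADC is the arithmetic mean over directions. The b = 0
image may be acquired once and shared; the fit mirrors it into each
direction. A negative mean ADC marks the voxel invalid.

**Dynamic contrast-enhanced (DCE) analysis.** The dynamic series
(TR = 3 ms, flip 7°, Δt = 3.5 s, 15 min, bolus at 2 min) is converted to
concentration per voxel: the effective amplitude A = M0·sin α follows from
the mean pre-injection signal and the independently mapped pre-contrast R1
by inverting the SPGR equation; each frame is then inverted via
E1 = (A−S)/(A−S·cos α), R1(t) = −ln E1/TR, and
[CA](t) = (R1(t) − R1,pre)/r1 with r1 = 3.53 mM⁻¹s⁻¹ (gadoterate at 7 T).
Frames with E1 outside (0, 1) have no physical inversion and propagate as
NaN. The analytic inversion (rather than a lookup table) was chosen for
exactness and testability.

The arterial input function is a population bi-exponential,
Cp(t) = A1·e^(−t′/τ1) + A2·e^(−t′/τ2) with A1 = 5.36 mM, A2 = 1.27 mM,
τ1 = 5.36 s, τ2 = 915 s, t′ = t − onset, zero before bolus arrival. The
onset is pinned to the injection time with no dispersion or delay term.
Tissue uptake follows the standard one-compartment Tofts-Kermode model,
Ct(t) = K^trans ∫₀ᵗ Cp(τ)·exp(−K^trans(t−τ)/v_e) dτ, evaluated in closed
form (a sum of exponentials per AIF term, with an explicit limit at
k_ep = 1/τ). K^trans is carried in min⁻¹ at every interface and converted
to s⁻¹ exactly once, inside the forward model; a unit-guard test pins the
60× factor. The voxelwise fit is bounded NLLS over
(K^trans ∈ [0, 10] min⁻¹, v_e ∈ [10⁻³, 1]) with analytic gradients and a
4-point multi-start (K^trans ∈ {0.05, 0.5} × v_e ∈ {0.1, 0.4}), keeping the
best-SSE solution; fit R² is computed on the concentration curve about its
mean, and time-to-peak is the argmax of the measured curve relative to
injection.

**Enhancement classification and QC.** A voxel is non-enhanced when the
median concentration over all post-injection frames is below 2× the
standard deviation of its pre-injection frames, expressed in apparent
concentration units (the pre-contrast frames pass through the same
conversion; comparing in raw signal space is available as a switch). The
median is taken over all frames after onset, the SD per voxel, and a flat
identically-zero curve is classified non-enhanced. K^trans/v_e averages
include only voxels that are (1) enhanced, (2) have fit R² > 0.80 strictly,
(3) peak before 800 s after injection, and (4) carry physiologically
realistic values (K^trans ≥ 0, 0 ≤ v_e ≤ 1); per-criterion failure counts
are returned for audit. A configurable minimum count of included voxels
(default 10) guards ROI averages computed from nearly empty masks.

**Cohort statistics.** Tumor volume integrates voxel volumes
dx·dy·(slice thickness + gap) over the ROI — slices tile space at the
1.1 mm pitch, so the gap is included (configurable). ROI summaries run over
valid voxels only and flag an empty intersection as undefined rather than
zero. Two-group comparisons follow the Levene-gate convention: classical
(mean-centered) Levene's test at α = 0.05 selects the pooled-variance or
Welch two-tailed t-test; longitudinal contrasts use the paired two-tailed
t-test. No multiplicity correction is applied (per-comparison α = 0.05).
Degenerate inputs (zero variance in both groups, or zero within-pair
variance) are flagged explicitly, with p reported at machine resolution
instead of from an undefined t distribution.

## The digital phantom

The phantom emulates a subcutaneous hind-limb tumor on a 2D multi-slice
grid (default 4×4 cm² in-plane FOV, 1.0 mm slices with 0.1 mm gap): an
axis-aligned ellipsoidal tumor with a 2-voxel rim shell, embedded in muscle
under a 1-voxel skin ring, inside a background margin. Default tissue
values are round numbers representative of this tumor model at 7 T, not
fitted to any dataset: tumor T1 = 2000 ms, T2 = 40 ms,
ADC = 0.7×10⁻³ mm²/s, K^trans = 0.2 min⁻¹, v_e = 0.3; muscle 1800 ms,
25 ms, 1.4×10⁻³, 0.08 min⁻¹, 0.12; skin 1600 ms, 30 ms, 1.2×10⁻³,
0.10 min⁻¹, 0.20. The B1 deviation field ζ is a smooth second-order
polynomial rescaled into [0.9, 1.1] (the measured correction map's shape is
not otherwise constrained). ADC is isotropic by default; the per-direction
ground-truth slots exist for anisotropic studies.

Every series the pipeline consumes is simulated from the same equations the
fits invert — including the B1-null series, which follows the
absolute-valued linear null model the correction fit assumes — so noiseless
simulate→fit round trips are exact up to solver tolerance. That is the
point: the phantom validates the estimators and their plumbing (units,
masks, geometry), not the physics the signal equations idealize away. It
deliberately omits EPI distortion, slice profiles, partial volume beyond
voxelization, motion, k-space effects, B1 effects on the AIF, and
per-subject AIF variability; passing tests therefore bound estimator error,
not acquisition artifacts.

**Noise.** Gaussian by default (the high-SNR regime of magnitude data);
Rician available, replacing S by |S + complex noise| as magnitude
reconstruction does. "SNR 50" in tests means sigma = (series peak tissue
signal)/50 per series: for the multi-echo and diffusion series the peak is
the equilibrium signal m0, while the short-TR gradient-echo series (VFA,
dynamic) have intrinsically lower peaks and receive proportionally lower
sigma — as per-sequence signal averaging produces on a scanner.

**Treatment effect.** Therapy response is parametric per timepoint: a
contiguous innermost fraction of tumor voxels (ranked by ellipsoid radius)
has K^trans set to 0 (vascular shutdown), the rest of the tumor gets
K^trans scaled and v_e shifted, and ADC/R1/R2 are scaled. Defaults encode
the qualitative PDT response pattern: directly post treatment a 45% core
with halved peripheral K^trans and raised v_e; at 24 h a 77% core with
ADC ×1.3; at 72 h additionally R1/R2 ×1.25 and ADC ×1.6. The non-enhanced
core dominates at 24 h while relaxation changes appear only late —
mirroring the observation that perfusion responds immediately and
endogenous contrast lags by days.

## Problem sizes and numerics

Recovery studies run on a 32×32×8 grid (≈1200 tumor voxels), chosen as the
smallest grid whose tumor comfortably holds the 500-voxel noisy-recovery
sample; the synthetic cohort uses 5 treated + 5 control subjects at
baseline and 24 h, matching a typical small-animal group size. Solver
tolerances are 10⁻¹² (xtol/ftol/gtol) throughout; the closed-form
tracer-kinetic model is cross-checked against an independent trapezoidal
convolution at dt = 0.01 s (integrated in time-since-bolus coordinates,
where the integrand is smooth), and the nonlinear T1/T2 fits against dense
grid searches with the amplitude profiled out analytically. Geometry
down-sampling from fine 3D slabs onto the 1.1 mm multi-slice pitch averages
all thin slices whose centers fall in each target window (windowed
averaging anti-aliases; plain decimation does not). Seeds propagate through
`numpy.random.default_rng`/`SeedSequence`, so every simulation is
bit-reproducible given (inputs, seed).

## Known limitations

- The standard (not extended) Tofts model: no plasma-volume term v_p, so
  highly vascular voxels alias plasma signal into K^trans/v_e.
- The population AIF is fixed; no bolus-arrival estimation or dispersion.
- Mono-exponential T2 and ADC (no multi-compartment, IVIM, kurtosis, or
  full tensor — three orthogonal directions are averaged).
- The phantom's compartments are piecewise constant; real tumors are
  heterogeneous, so cohort-level effect sizes from the phantom are not
  in-vivo effect sizes.
- Enhancement classification uses a per-voxel pre-contrast SD; pooled-ROI
  thresholds would behave differently at very low SNR.
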