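# Methods

This note documents the models, numerical choices and known limitations of
the package. It is the reference for why the defaults are what they are;
the README shows how to run things.

## Unit conventions

Offsets are ppm, converted with a configurable proton frequency
f0 = 300.06 MHz (7 T): Δω [rad/s] = 2π · Δ[ppm] · f0[MHz]. Saturation
amplitude B1 is µT with ω1 = γB1, γ = 2.675×10⁸ rad s⁻¹ T⁻¹. Relaxation
times are ms (T2,MT in µs), rates Hz. Signals are normalized (s0 = 1).

## Relaxometry

T1,obs is fitted from a five-point magnitude inversion-recovery series,
S(TI) = s0·|1 − 2e^(−TI/T1) + e^(−TR/T1)|, with TR = 10000 ms and ideal
inversion assumed (no efficiency factor). Magnitude data lose the polarity
of the recovery curve and the |·| kink creates local minima, so the fit
restores polarity explicitly: the null lies next to the smallest sample,
both candidate sign patterns are fitted with the smooth signed model, and
the better fit wins. This recovers T1 exactly on noiseless series across
the whole physiological range (validated against a cycled longitudinal
Bloch integrator to 1e-9).

T2,obs comes from a one-parameter fit of the continuous-wave
direct-saturation steady state (exact single-pool Bloch solution, verified
against time-domain propagation to 1e-12) to the B0-corrected WASSR
spectrum within ±1 ppm, with T1,obs fixed. Supplying a biased T1
propagates into T2 with the sign given by ∂Z/∂R1 > 0; the tests pin this
behaviour.

## Super-Lorentzian lineshape

g(Δf) = √(2/π) ∫₀¹ du T2/|3u²−1| · exp(−2[2πΔf·T2/(3u²−1)]²), the
orientation average for motion-restricted protons. It is normalized over
angular frequency (∫g dω = 1) and diverges logarithmically at Δf = 0; for
|Δ| < 1 ppm it is evaluated at 1 ppm (constant extrapolation — the fitted
windows never come closer than 3 ppm, so this only matters when the
two-pool model is evaluated near water, where the MT term is dominated by
direct saturation anyway). Two evaluation paths exist: adaptive
Gauss–Kronrod quadrature split at the singular point u = 1/√3 (reference;
agrees with a 10⁶-point Riemann sum to better than 1e-6 relative), and a
vectorized path through a cached log–log cubic spline of the 1-D profile
F(x), x = 2πΔf·T2 ∈ [1e-5, 25] (3000 knots; ≤1e-7 relative error against
quadrature). The spline backs the forward model so whole offset grids over
thousands of voxels evaluate in milliseconds.

## Two-pool MT model and fit

The steady state of the coupled longitudinal equations (free pool with
Lorentzian saturation rate, semisolid pool with super-Lorentzian rate,
exchange R_MT·M0,MT forward / R_MT back) is used in closed form; it agrees
with a time-domain Bloch–McConnell integrator (full transverse dynamics on
the free pool) to better than 1e-10 across the protocol's (B1, Δ, M0,MT)
range, because eliminating the transverse components at steady state is
exact for CW irradiation.

R1,MT is fixed at 1 s⁻¹ (conventional; configurable), and R1,F is
constrained by requiring the observed mono-exponential R1 to be the slow
eigenvalue of the longitudinal exchange matrix:
R1,F = R1,obs − R_MT·M0,MT·(R1,MT − R1,obs)/(R1,MT − R1,obs + R_MT).

The fit is bounded trust-region least squares over {T2,F, R_MT, M0,MT,
T2,MT} with bounds [5, 500] ms, [1, 100] Hz, [0, 0.5], [1, 30] µs,
initial values (40 ms, 20 Hz, 0.05, 8 µs), and three restarts with
log-normal-jittered initials (best residual kept, seeded). Spectra at the
WASSR amplitude contribute only their |Δ| ≤ 1 ppm points. Because R_MT and
M0,MT trade off along constant-product curves, the product R_MT·M0,MT is
the quantity carried into statistics; the tests verify that generating
sets with equal products but different factors fit to the same product
within 5 %.

## CEST/rNOE isolation

Z_EMR is the fitted two-pool model evaluated at the measurement's low B1;
MTR_REX = 1/Z_lab − 1/Z_EMR (negative values retained), AREX = MTR_REX/T1
with T1 in seconds. The AREX denominator uses the measured T1,obs by
default; the constrained free-pool 1/R1,F can be selected
(`t1_source="free"`). Z_lab at 3.5/2.0/−3.3 ppm is read by linear
interpolation on the B0-corrected grid; the default low-B1 offset grid
contains these offsets exactly (as acquisitions targeting them would), so
no interpolation error enters at the peaks. A conventional subtraction
metric (Z_EMR − Z_lab) is available for comparison but is not the headline
output.

## Digital phantom generator

The phantom is a 2-D 64×64 slice laid out as a xenograft cross-section:
muscle rim, muscle/connective ring, tumour interior, offset elliptical
necrotic core, and a few 2×2 blood/edema specks. Each tissue class carries
Gaussian generative parameters (mean ± SD) for T1,obs, T2,obs, T2,F,
R_MT·M0,MT, T2,MT and a set of CEST/rNOE pools (offset, peak exchange
rate, Lorentzian width). Tumour- and necrosis-class means are the group
means reported for the two xenograft lines. Values never reported —
tumour-region T1/T2,obs, the DU145 tumour T2,F, all pool amplitudes, and
everything for muscle, muscle/connective and blood/edema — are package
choices: muscle is solid-like (short T1/T2, strong MT), connective tissue
similar with longer T2,MT, blood/edema fluid-like (long T1/T2, weak MT),
pool amplitudes of order 1 Hz in tumour, roughly halved in necrosis and
near zero in muscle, mirroring the qualitative contrast the maps show.

Within a region, voxel values are drawn from the region's Gaussian but
through spatially smooth fields (Gaussian correlation length 3 voxels)
with a shared latent "tissue state" carrying 70 % of the variance —
relaxation times rise and MT falls together where the state is high, the
way cellularity drives these properties jointly in tissue. Zero-SD regions
reproduce their means exactly. Draws are truncated at 5 % of the mean and
T2,obs is capped below T1,obs voxelwise.

The forward simulation produces, per B1 level, frames in acquisition
order with 667-ppm reference frames interleaved every five measurements:
WASSR (0.1 µT) from the single-pool direct-saturation model at
(T1,obs, T2,obs); high-B1 spectra (3, 6 µT; ±log-spaced 3–300 ppm) from
the two-pool model; low-B1 spectra (0.5, 2 µT; ±6 ppm plus the exact pool
offsets) from the two-pool model with pools injected inverse-additively,
1/Z_lab = 1/Z_2pool + T1·ΣR_ex,i(Δ) — a construction under which the
ground-truth AREX at a pool offset is exactly the generating R_ex sum, so
isolation accuracy is measurable without a multi-pool Bloch–McConnell
reference. Pools are injected only at 0.5/2 µT; the high-B1 windows are
MT-dominated and keeping them pool-free makes the noiseless MT round trip
exact. Corruptions: per-voxel B0 offsets from a smooth random polynomial
(default peak 0.1 ppm), multiplicative linear drift S·(1 + slope·k) over
acquisition index (default 1e-4/frame), and additive Gaussian noise on
magnitude (default SD 0.005·s0; Rician optional). The full Bloch–McConnell
integrator remains available as an oracle, not a generator.

What the phantom does not emulate: anatomy beyond concentric ellipses,
motion (so no registration stage), B1 inhomogeneity, Rician bias at low
SNR (unless enabled), B1-dependent labeling efficiency of the CEST pools,
and any mismatch between the two-pool model and real semisolid spectra.
Passing round trips therefore demonstrate estimator correctness under the
generating models, not robustness to model error in vivo.

## Preprocessing

Drift: straight line through the interleaved reference frames versus
acquisition index, fitted per voxel; every frame is divided by the line's
prediction, which also normalizes to Z. B0: one Lorentzian
(L = a·w²/(w²+4(Δ−c)²); init a = 1−min Z, c = argmin Z, w = 1 ppm) fitted
to the WASSR spectrum inside ±0.5 ppm; a shared-centre two-Lorentzian
(DE + broad MT, w init 50 ppm) variant for the 0.5/2 µT spectra. Points
with Z < 0.05 are excluded from B0 fits (degenerate near-null dip).
Spectra are re-centred by linear interpolation onto the nominal grid;
out-of-range points become NaN and are excluded from later fits, never
extrapolated. In the pipeline the low-B1 spectra are re-centred with the
WASSR-derived shift map: the B0 field is common to all spectra, and the
two-Lorentzian fit is measurably biased (~0.1 ppm) by the CEST/rNOE peaks
it does not model; the per-spectrum variant remains available
(`lowb1_b0_mode="lorentzian"`). High-B1 spectra are not B0-corrected
(log-spaced grids from 3 ppm make the correction immaterial). Masks are
eroded with the full 3×3 structuring element; voxels with |B0| > 0.5 ppm
(strictly greater) are excluded. T1/T2 maps are normalized by 4000/300 ms
for segmentation.

In the pipeline's ROI MT fit, the 0.1 µT window is not included: the
generator simulates WASSR from the observed-relaxation single-pool model,
whose dip width (T2,obs) is not the two-pool free-pool T2, and the
noiseless high-B1 data already identify all four parameters exactly. With
real data (one physical water line) including the DE window is standard;
`TwoPoolMTModel` accepts it.

## Segmentation

Observation matrix: normalized T1 and T2 maps plus all high-B1 frames for
the retained voxels, row-major order. FastICA (unit-variance whitening,
3 components, seeded) → NMI sorting → per-type weighting (2:3:1 for
22Rv1, 1:3:2 for DU145) → 5-component full-covariance Gaussian mixture
(3 EM initializations, up to 5 jittered re-attempts on degenerate
covariances) → hard max-posterior labels (posteriors also kept). NMI is
computed on uniformly 32-bin-quantized images with arithmetic-mean
normalization; a constant image has NMI 0 by definition. Label rules: the
cluster with the largest |mean IC1| is blood/edema; axes are reflected so
that cluster's mean is in the first octant; the remaining clusters, by
ascending mean IC2, are muscle, muscle/connective, necrosis, tumour
(DU145) or tumour, muscle/connective, necrosis, muscle (22Rv1); the
ascending direction for the 22Rv1 sequence is assumed by symmetry with the
DU145 rule. Ties in cluster means break by larger mixture weight.

Known limitation: these per-type assignment sequences encode IC polarities
of the cohorts they were derived on. On phantoms generated from the
reported group-mean parameters, the reflected IC2 axis consistently orders
the clusters muscle < muscle/connective < necrosis < tumour — the DU145
sequence — for both parameter sets: the necrotic DU145 class exceeds the
tumour class in every observable (longer T1 and T2, weaker MT), and the
blood/edema cluster that fixes the reflection always lies on the fluid
(tumour) side. Consequently the necrosis label lands correctly on 22Rv1
phantoms in most seeds while the tumour/muscle pair swaps, and no choice
of the free parameters can satisfy both sequences at once. The
segmentation acceptance test records this as a failing Dice bound for the
tumour class; sign-flip invariance and the mechanics of every step are
verified independently.

## Statistics and reporting

The statistical unit is one animal's ROI mean per region and metric.
Comparisons are classical two-sided pooled-variance Student's t-tests
(df = nₐ + n_b − 2; Welch available behind a flag), starred ** for
p < 0.01 and *** for p < 0.001, with no multiple-comparison correction.
Pooled-t p-values are cross-checked against a permutation oracle in the
tests. Calliper tumour volume is length × width²/2. Report bundles
(region summaries, test tables, ROI spectra, run-parameter JSON) are
written with fixed float formatting so identical inputs give
byte-identical files.

Cohort-level operating characteristics are computed by direct simulation
of per-animal Gaussian ROI means: at the reported tumour-region MT-effect
group values (1.8 ± 0.2 vs 1.2 ± 0.1 Hz, n = 32 vs 34) the comparison
reaches p < 0.001 in ≥95 % of replicates, while identical-parameter
cohorts stay below a 5 % false-*** rate.

## Problem sizes and tolerances in the test suite

Unit tests use 16–32 voxel grids and 50–200 Monte-Carlo replicates; the
end-to-end segmentation check uses ten 64×64 phantoms at noise SD 0.01
(~17 s each); oracle-equivalence checks run a 125-point (B1, Δ, M0,MT)
grid against the Bloch–McConnell integrator at 1e-4 and the lineshape
Riemann sum at 1e-6 relative. Noiseless round trips assert ≤1 % (≤2 % for
the four-parameter MT fit at the printed region sets, per the coupling),
Monte-Carlo means are asserted within two standard errors, and the near-
null CW water dip — unrepresentable on the sampled grids by linear
interpolation and excluded from all fits — is excluded from spectrum-
reconstruction assertions.
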