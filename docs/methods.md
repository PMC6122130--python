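# Methods

`lowbafd` implements a complete, testable analysis chain for single-shell,
low-b-value diffusion MRI — the acquisition regime of routine clinical
scanners (b = 1,000 s/mm², one b0 volume, 30 encoding directions on a half
sphere, 2 mm isotropic voxels). Because no suitable public dataset ships with
the package, every stage is validated on synthetic phantoms whose
microstructure is known exactly. This note records the models, the numerical
choices, and what the phantom validation does and does not establish.

## Phantom forward model

Each voxel is a mixture of fiber populations and an isotropic pool. A fiber
population with direction **n**, volume fraction vf and intra-axonal fraction
f_ic contributes a perfectly restricted "stick" (zero radial diffusivity) and
an axially symmetric extra-cellular "zeppelin" sharing **n**:

    S(g, b)/s0 = f_csf · exp(−b·d_csf)
               + Σ_k vf_k · [ f_ic,k · exp(−b·d_ax (g·n_k)²)
                 + (1 − f_ic,k) · exp(−b·(d_r + (d_ax − d_r)(g·n_k)²)) ]

Defaults are literature-typical for adult white matter: d_ax = 1.7e-3,
d_r = 0.5e-3, d_csf = 3.0e-3 mm²/s, s0 = 1000. Magnitude noise is Rician,
formed from two Gaussian quadrature channels; SNR is stated on the b0
(sigma = s0/SNR). The default cohort emulates the study design this pipeline
targets: 13 independent noise realizations ("subjects") of one geometry at
SNR 30 — a realistic b0 SNR for a 1.5–3 T EPI acquisition; the paper-style
protocol parameters (direction count, b-value, voxel size, threshold values,
cutoff grids, subject count) are fixed as defaults and not tuned per run.

Geometries are built from straight rods and 180° arcs with voxel-tangent
fiber directions; where two bundles overlap the voxel carries both
populations at equal volume fractions. The crossing phantom (two orthogonal
rods, default 40³ grid at 2 mm; 20³ in the desk-scale preset) stands in for
the anatomy where tensor models fail — e.g. where the corticospinal tract
meets lateral association pathways. The WM mask is the labelled voxels plus a
configurable binary dilation (default 1 pass); dilated-but-unlabelled voxels
are isotropic with d = 0.8e-3 mm²/s, giving tractography a sub-threshold rim
to terminate in.

Gradient schemes are generated by electrostatic-repulsion descent with
antipodal symmetry and mapped to the z ≥ 0 hemisphere; any well-spread
half-sphere set is acceptable, and the optimizer is seeded so schemes are
reproducible.

What the phantom does **not** emulate: EPI/eddy distortions, motion, partial
voluming against gray matter and CSF geometry, axon-diameter distributions,
exchange, dispersion within a population, and T2 differences between
compartments. Passing tests therefore establish the internal correctness and
calibration of the estimators under the stated compartment model, not their
accuracy on in-vivo tissue.

## Tensor stage

Two fitters: weighted least squares on the log-signal (weights S²), and a
constrained signal-domain fit with D parameterized by its Cholesky factor
L L^T — positive semidefinite by construction — solved by Levenberg–Marquardt
with an analytic Jacobian, initialized from the (eigenvalue-clamped) WLS
solution, tolerances 1e-8, at most 100 iterations. Non-positive signals are
clamped at machine epsilon before the log transform. Because LL^T is PSD by
construction, any negative eigenvalue returned by the eigensolver is pure
round-off; eigenvalues above −1e3·eps·scale are snapped to zero
(`tensor_eigensystem(psd=True)`).

Scalars: FA, MD, AD = λ1, RD = (λ2+λ3)/2, and Westin shape coefficients
normalized by the eigenvalue sum, CL = (λ1−λ2)/Σλ, CP = 2(λ2−λ3)/Σλ,
CS = 3λ3/Σλ, chosen for the testable partition of unity CL + CP + CS = 1.
All-zero eigenvalues produce a zero sentinel with validity False.

## Response function and CSD

The single-fiber response is estimated from mask voxels with FA ≥ 0.7 (the
default selection threshold; configurable): gradients are rotated so the
principal eigenvector maps to +z, the b0-normalized signal is fit with even
zonal harmonics up to lmax, and coefficients are averaged over voxels, then
(in the multi-subject pipeline) across subjects to give a study-averaged
response.

Deconvolution uses the real, even-degree, antipodally symmetric spherical
harmonic basis and the Funk–Hecke relation s_lm = √(4π/(2l+1))·r_l·f_lm.
With 30 directions the full lmax = 6 system (28 coefficients) is solvable but
ill-conditioned for the unconstrained problem, so the initial fit uses
lmax = 4 and the constrained iterations regularize up to 6 (super-resolved
CSD): repeatedly solve

    min ‖A f − s‖² + λ_eff² ‖B_neg f‖²

where B_neg are the rows of a 300-direction Fibonacci constraint hemisphere
whose current amplitude falls below τ = 0.1 × the mean initial amplitude,
until the sub-threshold set is stable (≤ 50 iterations). λ_eff scales the
user-facing λ = 1 by 10·‖A‖_F/‖B‖_F; the factor was calibrated so that
converged fODFs show no sample below −1 % of the peak amplitude while the
single-fiber angular error stays below 1° — both properties are asserted in
the test suite. Peaks are located on a 1281-vertex subdivided-icosahedron
hemisphere, refined by a deterministic coarse-to-fine amplitude ascent
(final scale 0.04°), antipodally merged, and thresholded.

## Tractography

All four algorithms step bidirectionally from seed-voxel centers with fixed
step length, stopping on mask exit, FA < 0.2 (tensor methods), fODF amplitude
< 0.15 (CSD methods), turning angle > 60°, or length outside [10, 250] mm.
Probabilistic variants jitter repeat seeds uniformly within the voxel. The
backward half is conditioned on the realized first forward step so the
angular constraint also holds across the seed junction. Steps: 0.2 mm for
CSD methods, 0.5 mm for DTI methods (both configurable).

* `det_dti`: 4th-order Runge–Kutta on the trilinearly interpolated tensor
  field's principal direction (sign-aligned to the incoming direction).
* `prob_dti`: direction drawn from a Watson-like density exp(κ(μ·d)²) about
  the interpolated principal direction with κ = κ0·FA/(1−FA+ε), κ0 = 30 —
  a deliberate simplification of PICo-style uncertainty modelling that
  preserves the essential contract (dispersion shrinks as anisotropy grows).
* `det_csd`: the fODF peak nearest the incoming direction, found by amplitude
  ascent started at the incoming direction on interpolated SH coefficients;
  equiangular ties resolve to the higher amplitude by construction of the
  ascent.
* `prob_csd`: one direction per step sampled with probability proportional to
  the fODF amplitude over 24 candidates drawn uniformly in the 60° cone
  around the incoming direction — a single-step discretization rather than
  multi-step path integration; amplitude threshold 0.15 applies to candidates.

Voxel lookup everywhere maps world → continuous voxel coordinates through the
NIfTI affine and takes the half-open voxel [i−0.5, i+0.5) around each integer
index, so voxel centers coincide with the affine's integer coordinates.

## Density, overlap, and tract statistics

A track-density image counts **distinct** streamlines per voxel (segments
supersampled at ≤ half a voxel so no traversed voxel is missed; one
streamline increments a voxel at most once, making counts step-size
independent). Thresholding at c % of the map maximum is inclusive (count ≥
c/100 · max and count > 0), so the 0 % level equals the raw TDI; the
inclusive choice is a documented convention. Overlap Fraction is
100·|target ∩ reference|/|reference| on a common grid, with the
probabilistic-CSD reconstruction as the reference in the pipeline.
Thresholded TDIs also serve as ROIs over which FA, MD, CL, CP, CS, AD, RD are
averaged (invalid-fit voxels excluded and counted).

## Intra-axonal fraction and AFD

The radial-signal estimator isolates voxels with FA above a cutoff, takes the
highest fODF peak direction per voxel, reads the DW volume whose gradient is
most perpendicular to it (argmin |g·p| over weighted volumes only; ties to
the lowest index), and normalizes by that voxel's b0 (mean over b0 volumes).
For the two-compartment fiber this ratio is exactly
f_ic + (1−f_ic)·exp(−b·d_r) when a perpendicular gradient exists, plus a
small axial leak otherwise; at b = 1,000 and d_r = 0.5e-3 the extra-cellular
term contributes ≈ 0.18, which bounds how literally the ratio can be read as
f_ic. Rician noise biases the ratio upward (magnitude floor), a property the
tests assert rather than correct. The sweep runs at FA cutoffs 0.7–0.85; the
per-voxel records are computed once at the lowest cutoff and subset for the
higher ones, which is exactly equivalent to re-running the estimator.

AFD along a tract integrates, per visited voxel, the fODF lobe whose peak is
closest to the mean unsigned local streamline direction (principal axis of
the segment outer-product sum). Lobe membership assigns Gauss–Legendre ×
trapezoid quadrature samples (24 × 48 points; exact for the lmax = 6
expansion) to their angularly nearest peak; negative amplitudes are clipped.
A peak-amplitude mode is available as a flag. The whole-brain denominator for
voxel percentages is the phantom's brain mask (all non-background voxels).

## Statistical layer

Robust polynomial fits use Tukey-bisquare IRLS (c = 4.685, MAD scale),
delegated to statsmodels RLM. For the linear-vs-cubic comparison the cubic
fit's converged weights are frozen and both models refit under them so the
two weighted residual sums of squares are commensurable; both weighted and
unweighted SS are stored. The nested test is
F = ((SS_small−SS_big)/(df_small−df_big))/(SS_big/df_big) on
F(df_small−df_big, df_big); SS_big = 0 yields a perfect-fit sentinel
(p = 0, cubic), and a negative F under robust weighting clamps to 0. An
ordinary-LS mode exists for calibration simulations.

The repeated-measures test for a single within-subject factor forms
successive-difference contrasts, computes Hotelling's T² on the contrast
means, and uses the exact conversions Λ = 1/(1+T²/(n−1)),
F = ((n−k+1)/(k−1))·(1−Λ)/Λ with (k−1, n−k+1) df. At k = 2 this reduces
exactly to the paired t-test. Factor interactions are out of scope; in the
pipeline each factor (density cutoff, algorithm) is tested separately after
averaging over the other. The linear trend contrast is a one-sample t on
per-subject Σ w_j x_ij with centered scores; Bonferroni adjustment is
min(1, p·m). All-equal levels define Λ = 1, p = 1.

## Experiment orchestration and problem sizes

`run_experiment` derives every random stream from one master seed through
named substreams (`SeedSequence([master, stage-hash, subject])`, kept below
2³¹), so output tables are byte-identical across runs. The full-scale default
(40³ grid, 13 subjects, 100 probabilistic seeds per voxel) reflects the
complete study design; the desk-scale preset `ExperimentConfig.small()`
(20³ grid, 2 subjects, 6 seeds per voxel) exercises the identical code path
in under two minutes and is the configuration the test suite and the
acceptance script run. The repeated-measures tests require n > k−1 subjects
and are skipped below that.

## Known limitations

* The compartment model has no dispersion, exchange, or compartment-specific
  T2; the intra-axonal interpretation of the radial ratio inherits those
  assumptions.
* `prob_dti` and `prob_csd` are simplified samplers (Watson surrogate;
  single-step cone sampling) and should not be read as reimplementations of
  PICo/Bingham or multi-step fODF path integration.
* Response estimation assumes enough high-FA single-fiber voxels (≥ 20);
  isotropic or uniformly crossing data correctly raise an error rather than
  degrade silently.
* The lmax = 6 basis cannot represent a true delta; converged fODF peak
  amplitudes are regularization-dependent, which is why amplitude *ratios*
  and lobe *integrals*, not raw peak heights, carry the quantitative claims.
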