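# Methods

## Tensor model and scalar metrics

Each voxel carries a symmetric apparent-diffusion tensor **D** (mm²/s),
stored as six components in lower-triangular order (Dxx, Dxy, Dyy, Dxz,
Dyz, Dzz). With eigenvalues λ₁ ≥ λ₂ ≥ λ₃ and mean λ̄, the four scalars are

- MD = λ̄ (= trace(D)/3),
- L = √Σλᵢ², the Frobenius norm of D (total diffusion magnitude),
- q = √Σ(λᵢ − λ̄)², the eigenvalue dispersion (pure anisotropy),
- FA = √(3/2)·q/L, defined as 0 at the zero tensor (continuity convention).

These satisfy q² + 3·MD² = L² exactly and are rotation-invariant; all four
are symmetric functions of the spectrum, so degenerate eigenvalues need no
tie-breaking. Naming follows the convention in which q is the anisotropic
component and L the total magnitude; the literature occasionally swaps the
two labels, but only this assignment is consistent with FA = √(3/2)·q/L.

Negative eigenvalues (possible after noisy fits) are retained when
computing MD, L and q — clipping them would bias diffusivity summaries —
while FA is clamped to [0, 1] to stay interpretable; such voxels are
flagged `nonphysical` and counted in the run log. All diffusivities stay
in mm²/s throughout; no unit rescaling happens inside the math core.

## Signal simulation and noise

The forward model is the monoexponential tensor signal
S(b, g) = S0·exp(−b·gᵀDg). Gradient schemes are single-shell: one b = 0
volume plus n uniform unit directions produced by a Fibonacci-spiral
initialisation relaxed under antipodally-symmetric electrostatic repulsion
(pure spiral layouts can be rank-deficient at small n), then randomly
rotated per seed. Defaults: b = 1000 s/mm², 30 directions, S0 = 1000 —
typical rodent-brain DTI scale; all configurable.

Measurement noise is Rician: √((S+ε₁)² + ε₂²) with ε ~ N(0, σ²),
σ = 40 by default (SNR 25 at b = 0). σ = 0 is an exact pass-through, so
noiseless runs are bit-reproducible oracles.

## Tensor fitting

Ordinary least squares on log-signals against the design row
(−b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz, 1); exact on
noiseless data with zero residual. An optional one-pass weighted refit
(weights = squared predicted signals) counteracts the log-transform's
heteroscedasticity; it coincides with OLS on noiseless input. Signals are
floored at `min_signal` (default 10⁻⁶ × the maximum observed signal)
before the log; clipped entries are counted and surfaced. Voxels outside
the mask are never fitted. No positivity constraint is imposed — see the
nonphysical-flag policy above.

## The synthetic study

The phantom emulates a chronic closed-head-injury study: groups sham,
short-interval and long-interval (n = 6 each), imaged at day 50 and
day 90, with six box ROIs (cortex, CC, hippocampus, medial CC, EC, IC)
whose extents are grid fractions, so any grid from 6×6×1 up yields
non-empty, non-overlapping regions. Geometry is deliberately schematic:
ROI shape is irrelevant to the metric mathematics.

Each ROI has an eigenvalue profile and fibre direction (white-matter ROIs
strongly anisotropic with distinct orientations; cortex/hippocampus mildly
anisotropic). Group × ROI × timepoint effects act through two orthogonal
factors: `spread` scales eigenvalue deviations about their mean (changes
q and FA, preserves MD) and `scale` multiplies all eigenvalues (changes
MD, L, q proportionally, preserves FA). The default template encodes the
study's signed findings — short-interval cortex spread 0.85/0.82
(day 50/90), long-interval CC spread 1.10/1.12, short-interval EC and IC
scale 0.88 at day 90 only. Effect magnitudes of 12–18 % were chosen once
as realistic for contrasts reported significant at n = 6 given ~3–4 %
between-subject variation (Cohen's d ≈ 3); they are configuration, not
fitted values. Day-50 and day-90 profiles are independent entries with no
longitudinal drift model.

Biological variability is multiplicative eigenvalue jitter (3 % SD),
drawn once per subject and persisting across both timepoints so subjects
keep their identity in the repeated-measures design. Sub-seeds derive from
the master seed via `SeedSequence(master, spawn_key=(subject, timepoint,
purpose))`, giving independent, reproducible streams; the scheme is
recorded in the cohort metadata.

Synthetic immunohistochemistry counts follow
`count = round(max(0, intercept + slope·q_ROI + N(0, SD)))` on the
day-90 ground-truth ROI q for a histology subgroup of 4 sham / 3 short /
4 long subjects (terminal sampling). Defaults: GFAP slope −3×10⁵
counts/(mm²/s) — astrogliosis where anisotropy falls; NeuN slope +4×10⁵ —
neuronal loss co-occurring with low q; CD-68 slope 0 — microglial counts
carry no q relationship, matching a null association. Intercepts put
counts in the hundreds so integer rounding is negligible against the
count-noise SD. `gfap_noise_sd_for_target_r` inverts
r = slope·σ_q/√(slope²σ_q² + SD²) to hit a target population correlation.

## Statistics

The imaging analysis is a two-way mixed ANOVA per ROI × metric: group
(between subjects) tested against subjects-within-groups, time and
group × time against the subject × time stratum. The within factor has
exactly two levels, so sphericity holds trivially and no correction is
needed. The decomposition is implemented explicitly rather than via a
wrapper because the contract requires defined degenerate behaviour: an
effect with zero sum of squares reports F = 0, p = 1 even when its error
stratum is also empty (general-purpose packages return NaN there);
`pingouin.mixed_anova` serves as an independent oracle in the tests.
Balanced designs are exact (all sums-of-squares types coincide); under
unequal group sizes the cell-mean formulas above are used and documented
as such.

Post hoc group contrasts are Bonferroni-protected at raw p < α/3, in two
modes: per-day (default — contrasts are phrased "at day 50 / at day 90")
using that day's pooled within-group variance, or averaged over timepoints
using the between-subjects stratum. The multiplied-and-capped p is
reported alongside the decision. Histology counts get one-way ANOVA plus
Tukey HSD with studentized-range adjusted p (Tukey–Kramer form for the
unequal 4/3/4 subgroup). Correlation is the Pearson product-moment r with
a two-sided t-based p (n − 2 df) and the least-squares line; the r² = R²
identity is verified internally. All tests are two-sided.

## Monte-Carlo experiments and problem sizes

`dtiq.experiments` measures frequentist properties of the generator–
analysis pair over replicate cohorts. Replicates use a reduced phantom
(8×8×1 grid, 8 directions) so thousands of full cohorts run in minutes;
the *design* (3×6×2, six ROIs) is untouched. Because the reduced ROIs
hold 1–6 voxels instead of ~600–5,000, the reduced phantom lowers σ from
40 to 1.5 so the ROI-mean measurement precision — which scales as
σ/√n_voxels — matches the full-size phantom; subject-level variation then
stays dominated by biological jitter exactly as at full scale.

- Type-I calibration: 2,000 null cohorts (empty effect template); the
  group-test rejection rate at α = 0.05 is expected in [0.04, 0.06]
  (a ±2σ binomial band at that replication count).
- Effect detection: 200 cohorts under the default template; a contrast
  counts as detected when the day-90 Bonferroni contrast is significant
  with the configured sign. Measured rates are ≥ 0.97 per contrast.
- Correlation recovery: the GFAP coupling SD is calibrated (from
  dedicated calibration cohorts) to a population r = −0.65 between EC q
  and GFAP counts, pooling groups as in a pooled scatter analysis; 500
  cohorts then yield one n = 11 sample r each. The sample correlation is
  a biased estimator — E[r] ≈ ρ(1 − (1 − ρ²)/(2(n − 1))) ≈ −0.633 at
  n = 11 — so the recovery band around −0.65 is |bias| + 2×SEM ≈ 0.035,
  an analytic property of r, not an empirical adjustment. (With a
  group-mixture x distribution the realised bias is smaller than the
  bivariate-normal formula suggests; the band covers both cases.)

## Numerical choices

- Eigenvalues via `numpy.linalg.eigvalsh` (symmetric solver), reversed to
  descending order.
- A sum of squares is declared exactly zero below 10⁻¹² × the total SS;
  an F numerator that vanishes gives F = 0, p = 1; a vanishing error
  stratum under a real effect gives F = ∞, p = 0.
- FA of the zero tensor is 0; FA is clamped to [0, 1].
- NaN voxels inside an ROI (non-fitted) are excluded from means and from
  the reported voxel counts; an ROI with no finite voxels is an error.
- NIfTI volumes are written uncompressed so identical data produce
  byte-identical files; determinism checks compare raw bytes.

## Limitations

The phantom omits motion, eddy currents, susceptibility distortion,
partial-volume mixing and multi-compartment diffusion; ROIs are
piecewise-constant boxes, not traced anatomy; histology counts are an
explicit linear-Gaussian model, not a biophysical one. Passing tests
therefore demonstrate correctness of the decomposition, fitting and
statistical machinery under the stated generative model — not robustness
to real-acquisition artefacts. The rmANOVA is exact for balanced complete
designs; incomplete designs are rejected rather than imputed, and
unbalanced group sizes use cell-mean formulas that correspond to the
balanced decomposition rather than any particular regression-based type.
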