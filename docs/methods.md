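# Methods

## Surrogate model

The response surrogate is a polynomial-chaos expansion of the scalar exposure
metric E₉₉ₜₕ over the two field-orientation angles.  The inputs are treated
as independent, θ uniform on (0°, 180°) and φ uniform on (−180°, 180°); the
matching orthogonal family is Legendre on (−1, 1) after the affine
standardization ξ₁ = θ/90 − 1, ξ₂ = φ/180.  The basis is the tensor product
truncated at total degree p, of size P = C(p + K, K) with K = 2.

Two choices are worth stating explicitly because the moment identities depend
on them:

* **Orthonormal polynomials.**  The family used is √(2n+1)·Pₙ, orthonormal
  for the uniform density ½ on (−1, 1).  With an orthonormal basis the
  surrogate's mean is exactly the constant coefficient a₀ and its variance
  exactly Σ_{j≥1} a_j², which is how the per-tissue moments and CVs are
  computed (no sampling involved).
* **Graded-lexicographic index ordering** with the constant term first, so
  model files serialize deterministically and regression paths are
  reproducible bit for bit.

The open supports are honoured by clamping endpoint angles inward by one
machine epsilon instead of rejecting them; designs generated on [0, 1) grids
would otherwise hit the boundary.

## Fitting and model selection

Sparse selection uses the classical LARS path over the non-constant columns
of the basis matrix (columns centered and scaled to unit norm *only* inside
the correlation machinery; the constant column is always in the model).  The
candidate family consists of the intercept-only model plus one model per LARS
step, up to min(P, N−1) coefficients in total.  On every candidate the
coefficients are re-estimated by OLS on the original unscaled columns
("hybrid" estimates), because the downstream moment formulas need unbiased
coefficients on the orthonormal basis.  Candidates are scored by the
closed-form leave-one-out error

    err_LOO = Σᵢ ((yᵢ − ŷᵢ)/(1 − hᵢ))² / Σᵢ (yᵢ − ȳ)² ,

with hᵢ the hat-matrix diagonal — the relative (variance-normalized) form, so
thresholds are scale-free.  Ties go to the smaller model.  The corrected
(T-factor) LOO variant is deliberately not applied; plain LOO is the default
and the only implemented scorer.  Degenerate constant responses short-circuit
to the intercept-only model instead of failing (the relative error is
undefined there).

Validation is the percentage mean square error (pMSE) against an independent
uniform-random design of size S = N/2, and the fit is refined over an
ascending ladder of design sizes and degrees — default n_grid = (75, 150,
300), p_grid = (5, 10, 15), stopping at the first combination with
pMSE < τ = 0.5 %.  The grids are a package choice of a plausible refinement
ladder ending at the (N = 300, p = 15) operating point at which the degree-15
surrogate of the smooth virtual-solver response validates far below τ.  When
no grid point converges the best model is returned flagged, and the pipeline
exits non-zero.

## Experimental designs

* **Build set:** the unscrambled 2-D Sobol sequence, skipping the origin
  (skip = 1), mapped affinely onto the angle box.  Unscrambled + skip makes
  designs bit-reproducible, and growing N reuses the earlier points (nested
  by construction).
* **Validation and sweep sets:** i.i.d. uniform in the angles, seeded.  Being
  a continuous distribution, validation points differ from the build set with
  probability one; Sobol designs additionally assert distinctness.
* Every stochastic stage takes an explicit seed; the pipeline config carries
  three named seeds (validation, sweep, noise) and embeds a config hash in
  every artifact.

## Virtual solver (synthetic observations)

The deterministic solver is the exact interior eddy-current solution of a
homogeneous conducting triaxial ellipsoid in a uniform sinusoidal field: for
the field component along z,

    E⁽ᶻ⁾ = ω B_z /(a² + b²) · (−a² y, b² x, 0),

and cyclically for the x and y components; all components share one phase, so
RMS amplitudes superpose linearly and |E| is even in the field direction
(antipodal symmetry is exact).  The solution satisfies the quasi-static field
equations and zero normal current on the body surface identically, vanishes
on the central axis of each cross-section, and scales linearly in both B and
frequency — so the synthetic observations carry a *physical* orientation
dependence, not an arbitrary test function.

E₉₉ₜₕ of a tissue is the 99th percentile (linear-interpolation order
statistic) of |E| over a regular point cloud filling the tissue ellipsoid;
grid steps are chosen automatically to target ~2000 points per region (2 mm
cap, matching the granularity of small averaging volumes).  Optional
multiplicative log-normal noise with CV ≤ 5 % emulates numerical uncertainty
of a discretized solver; it is off by default and seeded per
(tissue, design) when on.

The gestational-age fixtures place a fetus ellipsoid (volumes matching ~15 g,
~1.7 kg and ~2.7 kg) inside a maternal body ellipsoid (semi-axes 0.13 ×
0.20 × 0.85 m), with 15 / 17 / 26 tissue sub-regions laid out as fractions of
the fetus.  Tissue names follow commonly segmented fetal tissues; entries
beyond the well-known organs are synthetic padding to reach the per-age
counts.  Brain and CSF are flagged as CNS-of-head tissues (the stricter
0.02 V/m restriction); the spinal cord is not ("of the head"), and no retinal
region exists, so the eye lens is not flagged.  The fetus geometry is chosen
so that the whole-body worst-case orientation is front-to-back at 3 and 9
months and lateral at 7 months: which induction cross-section dominates is
controlled by the fetal extents along x and y, mirroring how fetal size and
position select the worst-case axis.

What the generator does *not* emulate — and hence what passing tests do not
establish about anatomical dosimetry: heterogeneous conductivities,
tissue-interface boundary corrections, the 2×2×2 mm³ vector averaging of a
voxelized solver, realistic organ shapes, and fetal-posture variation.  The
pipeline reproduces the *procedure* (surrogate construction, validation and
exposure statistics), and its absolute mV/m outputs are only
order-of-magnitude realistic.

## Exposure statistics

The orientation sweep evaluates the surrogate on M = 10 000 random
orientations *uniform in the angles* — the input probability model — and
takes mE₉₉ₜₕ as the sweep maximum; because such a maximum is a noisy
estimator, the per-tissue report also carries the surrogate maximum over a
deterministic 1° × 1° grid as a cross-check (cheap on a polynomial).  WS% is
100·mE₉₉ₜₕ/E_lim with E_lim selected by the CNS-of-head flag.

Band classification uses v ≥ 0.9·max, 0.8·max ≤ v < 0.9·max and
0.7·max ≤ v < 0.8·max (the 70 % threshold is the 3 dB amplitude window).
Solid angles of orientation sets are Monte-Carlo estimates with sin θ
importance weights, Ω = (2π²/M) Σ_member sin θᵢ, correcting the angle-uniform
sampling density to spherical area; a standard error accompanies each
estimate, and the four band angles sum to 4π within Monte-Carlo error.
Because the physics is even in the field direction, high-exposure regions
always occur in antipodal pairs; reported band solid angles cover the whole
sphere, i.e. both lobes of a pair jointly.

## Numerical choices and degenerate inputs

* Legendre evaluation by the stable three-term recurrence (all degrees at
  once); orthonormality holds to 1e−10 under Gauss–Legendre quadrature up to
  p = 15.
* LARS stops early (with a log message) on a singular active Gram matrix or
  an exhausted residual; selection skips candidates whose LOO is undefined
  (leverage 1) and only fails if every candidate does.
* pMSE requires strictly positive validation values; observation tables are
  validated on read (finite, positive, aligned), with errors naming the
  offending row and column.
* Solid-angle estimation refuses sweeps below 100 points; band thresholds
  must be strictly increasing within (0, 1).

## Problem sizes

Default problem sizes — 300 × 136 basis matrices, ~10⁵-point clouds for the
whole-body region, 10⁴-orientation sweeps — run the full 27-tissue 9-month
pipeline in well under a minute on one CPU.  Tests use coarsened point clouds
(`resolution_scale`) and smaller sweeps where full resolution adds nothing to
the property under test.

## Known limitations

* Only K = 2 uniform inputs are exercised; other input distributions
  (Hermite, Laguerre, Jacobi families) are extension points, not features.
* The LARS implementation returns the inclusion order only (no lasso
  modification, no coefficient path), which is all the hybrid scheme needs.
* mE₉₉ₜₕ from a finite sweep underestimates the true surrogate maximum
  slightly; the dense-grid cross-check bounds the gap.
* The axis convention (which angle pair is "front") is a declared package
  convention; data produced under another convention must be mapped before
  import.
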