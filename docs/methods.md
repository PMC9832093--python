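# Methods

This note documents the models behind `silicofem`, the defaults that
matter, and what the phantom-based validation does and does not show.

## The pipeline in one paragraph

A pair-matched source cohort of isotopological femur models (identical
tetrahedral connectivity, per-subject node coordinates, four anatomical
landmarks, element-wise apparent density and Young's modulus) is flattened
into one vector per subject and decomposed by PCA into a statistical
shape-and-appearance atlas.  New subjects are synthesized by sampling each
principal component's empirical score distribution independently
(inverse-transform sampling), reconstructing, and passing mesh quality
control.  Every subject — source or synthetic — then runs through a
side-fall strength model over a 7 × 4 orientation grid, a lognormal
fall-load model turns the failure loads into a per-fall fracture
probability `P` and the one-year risk `ARF0 = 1 − (1 − P)^0.65`, and the
source and expanded cohorts are compared distributionally (mixture fit,
KS, normality, equal-error-rate stratification).

## Phantom cohort generator

The generator replaces CT-derived anatomies with a parametric solid:
a radius profile (shaft → trochanteric flare → tapered neck → spherical
head) revolved around the axial coordinate, the head offset applied as a
volume-preserving lateral shear, meshed by mapping a hexahedral lattice
through a smooth square-to-disc map and splitting each cell into six
tetrahedra (conforming Kuhn subdivision, watertight by construction).
Per-subject variation is a random anisotropic scale (±6 %) plus a random
quadratic warp (±4 % of the mesh half-extent) applied identically to
nodes and landmarks, so topology is invariant by construction.

Materials: elements whose centroid lies within 3.6 mm of the surface get
cortical apparent density 1.8 g/cm³, interior elements trabecular
0.35 g/cm³, plus a smooth random cosine field (SD 0.05 g/cm³, 30 mm
wavelength); the whole field is multiplied by a per-subject scale
(lognormal-free normal, SD 0.08) and, for fractured members, by a deficit
drawn uniformly from (0.72, 0.90).  Young's modulus follows the power law
`E = 6850·ρ^1.49` MPa, a widely used femoral relation; both constants are
configuration points and any monotone law preserves the pipeline.

Pair matching mirrors a retrospective case-control design: age
(75 ± 9 y), height (158 ± 6 cm) and weight (63.6 ± 13.4 kg, correlated
with the control member's aBMD at Pearson r = 0.4) are drawn once per
pair; only the density deficit distinguishes the fractured member.  The
deficit range is a free parameter of the generator — the fractured/control
density contrast of the emulated population is not published — and was
fixed, together with the geometric and material defaults above, so that
the phantom cohort's strength scale overlaps the fall-load scale (below)
and the label-wise ARF0 moments land near the reference mixture
(29 ± 12) % / (55 ± 13) % that the pair-matched design implies: measured
at default resolution, controls 0.30 ± 0.14 and fractured 0.54 ± 0.17.
These defaults are the study conditions of the package's own experiments
and are not tuned per run.

What the phantoms do **not** emulate: real femoral anatomy (the solid is
a stylized sphere-neck-shaft), CT partial-volume and calibration effects,
intra-cortical porosity gradients, or morphology–density correlations
beyond the simple height-scale coupling.  Consequently the validation
shows that the *pipeline logic* (isotopology, atlas algebra, sampling
fidelity, risk monotonicity, stratification) behaves correctly, not that
its absolute strengths or risks match any clinical population.

## Atlas

The subject vector is `[node x,y,z interleaved ‖ 4 landmarks ‖ element
moduli × block_scale]`.  By default `block_scale = 1` — literal
concatenation of millimetre coordinates and MPa moduli; an option
equalizes total block variances instead, since the appropriate weighting
between shape and appearance blocks is a genuinely open modelling choice.
PCA is computed by thin SVD of the mean-centred `n × p` matrix (never the
`p × p` covariance; for `p ≫ n` this is the Gram-matrix eigenproblem).
Components below 1e−12 of the leading variance are dropped as numerical
rank noise.  A 94-subject full-rank cohort therefore yields exactly 93
components; on phantom cohorts ~20–45 components explain 95 % of the
variance (the smooth warp family is low-dimensional; the material noise
field supplies the rest of the rank).

## Cohort expansion

Empirical inverse CDFs use Hazen plotting positions `p_i = (i − 0.5)/n`
with piecewise-linear interpolation and clamping to the training
min/max — sampled scores can never leave the training support.  The
default uniform band (0.025, 0.975) mimics a ±2 SD restriction.
Components are sampled independently (PCA scores are uncorrelated; at
n = 10,000 the sampled cross-correlations stay below 0.05, and the
full-band marginal KS distance to the training scores stays below 0.03).
QC rejects meshes with non-positive element volumes or aspect ratio
(longest edge over `2√6·inradius`) above 20; failed subjects remain in
the cohort table with an explicit status.

## Covariates

The areal-BMD surrogate integrates ρ·V over a neck box (centred midway
between head-centre and trochanter landmarks, width 0.15 of their
distance) and divides by the box area projected along the
antero-posterior axis, converted to g/cm².  On the default phantom it
yields ≈ 1.0 ± 0.16 g/cm² — higher than DXA femoral-neck values because
the snug box sees the full bone path length; it is monotone in density,
which is all downstream stages require.  The T-score reference defaults
to 0.858 ± 0.120 g/cm² (young-adult female femoral-neck convention) and
is configurable.

Weight is assigned as `a + b·aBMD + ε` with
`Var(ε) = Var(aBMD)·b²·(1 − r²)/r²`; height by the bilinear analogue with
`Var(fitted)·(1 − r²)/r²`, which reduces to the former in the
single-predictor case (this two-predictor construction is this package's
derivation from the Pearson definition).  Non-positive draws are re-drawn
(up to 100 rounds, logged).  Age is not assigned to synthetic subjects:
nothing downstream consumes it.

## Side-fall strength surrogate

The reference boundary-value problem — non-linear frictionless contact
with a rigid plane plus a knee hinge — is replaced by a linear surrogate:

- constant-strain 4-node tetrahedra, Poisson ratio 0.3;
- the 1000 N trial load spread over femoral-head surface nodes (within
  1.35 × the minimum head-centre-to-surface distance);
- the distal 6 mm band of the shaft cut pinned (hinge stand-in);
- the surface patch furthest along the load direction (5 mm deep)
  restrained against motion along that direction by penalty
  (contact stand-in; penalty 1e8 × the stiffness diagonal maximum).

Orientation convention: the reference fall axis points from the head
centre toward the greater trochanter; the antero-posterior angle rotates
it about the lateral axis, then the medio-lateral angle about the
antero-posterior axis, both in the subject's landmark-derived local
frame.

Element strain tensors are averaged tensor-first over 3 mm spheres of
element centroids around each surface node (an empty sphere falls back to
the nearest element), then principal values are taken.  The failure load
scales the trial magnitude by `min over nodes of min(0.0073/ε₁,
0.0104/|ε₃|)` — exact under linearity, so it is independent of the trial
magnitude (verified to 1e−9 relative) and homogeneous of degree one in a
global modulus scale.  The criterion is evaluated on the proximal surface
only (above the trochanter level minus 15 mm) and away (8 mm) from
loaded/constrained nodes: the clamped distal cut carries the surrogate's
artificial peak cantilever moment and would otherwise define failure.
The CST element reproduces constant-strain states exactly (patch test:
tip displacement of an axially loaded bar matches FL/EA to solver
precision).

Known limitations: no contact, no geometric or material non-linearity,
and at ~650–2000 elements the 3 mm averaging sphere usually contains one
or two centroids, so the averaging is closer to nearest-element smoothing
than at study-scale resolution.

## Fall load and risk

Peak impact force is lognormal with log-scale σ = 0.25 and median
`F0 = √(2·K_eff·m_eff·g·h_hip)`, `m_eff = weight/3`,
`h_hip = 0.51·height`, `K_eff = 71 kN/m` — a single-mass impact energy
balance standing in for a full multiscale fall-dynamics model; every
constant is configurable and the distribution sits behind an
`exceedance(load)` interface so other models plug in.  At the cohort's
mean anthropometrics F0 ≈ 4.8 kN.  Per-orientation fracture probability
is the lognormal tail above the failure load; `P` is the unweighted mean
over the 28-point grid (the natural quadrature on a uniform grid;
a weighted option would be a one-line change).  `ARF0 = 1 − (1 − P)^λ`
with λ = 0.65 falls/year; `ARF0 ≤ P` for λ < 1.

## Statistics

The univariate two-component Gaussian mixture is fitted by plain EM:
median-split initialization (deterministic), responsibilities via
log-sum-exp, variance floor 1e−6 × sample variance, stop at
log-likelihood gain < 1e−8 or 500 iterations.  The log-likelihood is
non-decreasing per iteration; on 10,000 draws from the reference mixture
(29/55 %, SDs 12/13 %) the component means are recovered within ±2
percentage points, and the fit agrees with scikit-learn's EM on the same
data (used in tests as an independent cross-check only).  The
equal-error-rate threshold scans midpoints between consecutive sorted
unique scores, minimizes |FPR − FNR|, and breaks ties toward the lower
threshold; classification is "fractured iff ARF0 > threshold" with ties
to non-fractured.  KS and the normality battery delegate to scipy.

## Problem sizes and reproducibility

Default experiment sizes: 47 pairs (94 subjects), 1080 synthetic
subjects, ~2000-element meshes; the bundled end-to-end check runs 47
pairs expanded to 500 synthetic subjects at default resolution in a few
minutes on one core.  At those sizes the source-cohort equal-error-rate
threshold splits the synthetic cohort into fractions between roughly 0.4
and 0.55 depending on seed, the two-component mixture is preferred over a
single Gaussian by BIC (the margin varies seed to seed — from a few BIC
points to several tens), and the source-vs-synthetic KS test does not
reject.  The whole pipeline is a deterministic function of (config,
master seed): the master seed spawns per-stage child seeds, so stages can
be re-run in isolation from their on-disk artifacts with identical
results.
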