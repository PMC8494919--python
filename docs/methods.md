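# Methods

## Physical model

The forward problem is the 2-D conductivity equation ∇·(−σ∇V) = 0 on an
abdominal cross-section, discretized with linear (P1) triangles and
piecewise-constant conductivity σ (S·m⁻¹) per element. Coordinates are in
cm; because the P1 stiffness matrix is scale-invariant in two dimensions,
σ in S/m multiplies cm-based element matrices directly. The model is
per-unit-depth: a frame injecting I mA is interpreted as I mA per metre of
belt height, and voltages are reported in volts. The one place physical
length enters is the complete-electrode-model boundary term, where pad arc
lengths are converted to metres and the contact impedance is taken in
Ω·cm and converted to Ω·m. This convention is fixed here once to avoid
silent factor-of-100 errors.

Two electrode models are implemented:

- **point** — current injected at the centre node of each pad; admits the
  closed-form boundary potential u = (I/πσ)(ln|x−x₋| − ln|x−x₊|) on a
  homogeneous disk, used for analytic validation, and makes the scaling
  identity V(ασ) = V(σ)/α exact;
- **complete** (default) — finite pads, contact impedance and shunting,
  the accepted physical model for belt systems. Default contact impedance
  is 50 Ω·cm (order of magnitude typical of gel ECG electrodes); with
  narrow pads and small contact impedance the model reproduces the point
  solution to < 0.1 %.

The system is grounded by a zero-mean constraint (nodal mean for the point
model, electrode-potential mean for the complete model) via one Lagrange
multiplier, keeping the matrix symmetric and differential voltages
invariant under electrode relabelling.

Stimulation follows the skip-*s* pairwise protocol: frame *e* drives
electrodes (e, e+s+1) and measures all offset-(s+1) pairs not touching a
drive electrode — *n* − 3 pairs per frame for the configurations used here
(the count is fixed by brute-force enumeration, which the tests pin down).
The study conditions are 32 electrodes, skip 4, 1–4 mA at 50 kHz; current
is an input and the solver warns outside 1–4 mA. A single real
conductivity at one frequency is modelled; the frequency is metadata.

## Meshing

Phantoms are outline + organ polygons. Triangulation is Delaunay over a
structured point set: boundary nodes by arc-length sampling (electrode
pads get ≥ 3 nodes each; organ-polygon boundaries are sampled at the
element scale so triangle edges follow them closely), interior nodes on a
hexagonal lattice, with triangles whose centroid falls outside the outline
discarded. Each element inherits the label of the innermost region polygon
containing its centroid. Electrodes are centred at equal arc-length
spacing, counter-clockwise from where the +x ray from the centroid meets
the outline; the default pad width is 1.2 % of the belt perimeter
(~2.5 cm pads on a ~100 cm outline — a config default, since pad width is
not a measured quantity). A region whose polygon area is smaller than the
squared element size raises a resolution error rather than silently
vanishing.

## Inversion

The solver minimizes the misfit ∅ = ‖V₀ − f(σ)‖ with penalty λ‖Γσ‖²,
iterating the regularized Gauss–Newton update with the adjoint Jacobian
J(k,e) = −z_kᵀ S_e u_d (one LU factorization serves all drive and adjoint
solves; S_e is the unit-σ local stiffness). Design choices:

- **Γ** is a graph Laplacian on shared-edge element adjacency, weight 1
  within a labelled region and 0.1 across region boundaries, so the prior
  smooths within organs and allows jumps between them. Γ depends only on
  geometry and labels and is built once; J is rebuilt every iteration.
  The penalty is applied to σ itself, not to σ − σ₀.
- **λ** defaults to α·tr(JᵀJ)/tr(ΓᵀΓ) evaluated at the starting point and
  held fixed, with α = 1 — the scale-invariant choice that puts both
  normal-equation terms at comparable magnitude. On the reference phantom
  the liver-mean estimate moves by < 2 % over α ∈ [0.1, 10] (and < 9 %
  over five decades), so the default is uncritical; the two-decade
  robustness is a regression test.
- **σ₀**: the iteration starts from the best-fitting homogeneous
  conductivity (bounded 1-D minimization of ∅ over log σ), which fixes
  the absolute scale.
- **Positivity and damping** are deliberate additions to the bare update:
  the iterate is floored at 5 % of σ₀, and a backtracking line search
  (step halved up to 7 times) accepts only non-increasing misfit. Two
  consecutive rejected steps terminate with `converged=False` — a result,
  not an exception.
- **Convergence**: relative iterate change ‖σₙ−σₙ₋₁‖/‖σₙ₋₁‖ < 10⁻³,
  max 25 iterations.
- In the strong-regularization limit the update is confined to Γ's
  nullspace (spatial constants), so σ stays uniform but its level still
  tracks the data — the correct behaviour for a Laplacian prior, and what
  the tests assert.

Liver conductivity is summarized as the area-weighted mean and spatial SD
over liver-labelled elements, matching the per-subject mean ± SD
convention of the cohort tables (the ± is interpreted as spatial SD over
the liver region).

## Synthetic cohort

The generator emulates the study population: overweight adults
(BMI > 25), PDFF ~ U(1 %, 28 %), liver conductivity σ = a − b·PDFF with
a = 0.355 S/m, b = 0.003 S/m per %, plus N(0, 0.012 S/m) subject-level
scatter — the weakest (linear, monotone-decreasing) law spanning the
0.27–0.35 S/m band of the printed cohort; no quantitative
conductivity-PDFF calibration exists, so this map is a modelling choice,
not an empirical claim. Noisy draws are floored at 0.02 S/m; a map that
is non-positive anywhere in the PDFF range is rejected at validation.
Demographics (height N(167, 8.5) cm, BMI N(34, 6.5) truncated > 25, waist
N(110, 14) cm, age U(26, 74), 4/19 male) are sampled independently of
PDFF by default — matching the null demographic correlations the analysis
stage should find — with optional correlation knobs for power studies.
Weight is derived from BMI and height so the BMI identity holds exactly.
Default n = 19 subjects with a 3/19 exclusion rate mirrors the study's
recruitment; pipeline-level checks use 16 kept subjects.

`subject_to_phantom` scales the base phantom isotropically so the outline
perimeter equals the subject's waist and sets the liver conductivity from
the map; per-subject meshes scale their element size with the subject so
relative resolution is constant. What the generator does **not** emulate:
3-D current paths, organ-shape variability beyond isotropic scaling,
electrode placement error, frequency dependence, and electrolyte
disturbances from comorbid disease (those exist only as an exclusion
flag). Passing pipeline tests therefore demonstrate methodological
soundness under the stated 2-D model, not clinical performance.

ROI averaging of a fat-fraction field uses small circular ROIs (default
5 mm²) with midpoint polar quadrature (exact for linear fields), the mean
of per-ROI means clipped to [0, 100] %.

## Statistics

Pearson r with two-sided t-test p (n − 2 df), OLS slope with t-based 95 %
CI, and the full grid {PDFF, EIT} × {BMI, age, waist, height, weight}
plus EIT vs PDFF. The Bonferroni family defaults to m = 4 — the four
demographic tests (age, waist, height, weight) run per outcome, the
family under which PDFF-vs-height at p = 0.016 is nominally but not
multiplicity significant (0.016 > 0.05/4); a pooled family (m = 8) is
available via `bonferroni_m`. Fixture exclusion policies: `study_n16`
drops subjects 4 (electrode malfunction), 14 (renal failure) and 18
(leukemia); `study_n18` drops only subject 4. Fixture-vs-printed checks
use ±0.02, the rounding precision of the tables.

## Numerical choices and problem sizes

Reference experiments use a 15 × 10 cm elliptical phantom with a 4.5 cm
liver disc meshed at 1.2 cm (~790 elements), fine enough that liver
recovery is noise- not discretization-limited while keeping a full
reconstruction under ~2 s; analytic forward validation uses a unit disk
at 0.06 cm (~2000 elements); Jacobian finite-difference checks use a
~120-element disk. Calibration simulations use 200 null cohorts (type-I
error) and 1000 replicates (CI coverage). All randomness flows through
explicit integer seeds (`numpy.random.default_rng`), and identical seeds
give bit-identical outputs end to end.

## Known limitations

- 2-D per-unit-depth physics; out-of-plane currents in a real abdomen
  bias absolute conductivity, which is one reason the synthetic pipeline
  cannot reproduce a clinical correlation coefficient, only its sign and
  strength class.
- Self-consistent inversion (same mesh for simulation and reconstruction)
  is used in recovery tests; this is intentional for validating the
  solver, and optimistic relative to model-mismatch conditions.
- Organ-boundary edges are followed by boundary-point sampling rather
  than hard constrained edges; region areas are accurate to ~1–2 % at the
  default element size.
- The exclusion flags of synthetic subjects mark confounding conditions
  but do not model their physiology.
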