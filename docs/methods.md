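# Methods

`craniogrowth` implements a complete, self-contained version of a
simulation-plus-morphometrics analysis of early postnatal human cranial
growth: an osmotic tissue-expansion finite-element (FE) model of brain and
masticatory-muscle growth deforming a neonatal skull, evaluated against a
normative landmark sample via Procrustes allometric regression, Cavalieri
stereology, and surface-distance fields.  All inputs are synthetic and
generated by the package itself, with known ground truth; this note
documents the models, the parameter choices, and what the synthetic inputs
do and do not emulate.

## 1. Synthetic head geometry

The head is a constructive solid meshed on a uniform voxel grid
(Freudenthal six-tetrahedra subdivision, all cells split identically, so
domain interfaces are conforming by construction and the mesh is a pure
function of its parameters):

* **endocranial cavity / brain** — ellipsoid with semi-axes
  (40, 55, 42) mm (volume ≈ 387 cm³, a realistic neonatal endocranial
  volume); x is lateral (midsagittal plane x = 0), y
  posterior-to-anterior, z inferior-to-superior;
* **skull** — 7 mm shell around the cavity with a circular basal opening
  (foramen-magnum analogue, radius 0.15·a_x, posterior of centre) and a
  facial block fused to the anterior shell;
* **mandible** — a block below the skull plus two condylar ramus columns
  that rise into the lateral basicranial shell (a temporomandibular-joint
  analogue).  Articulating the jaw matters for the scenario comparisons:
  with a free-hanging mandible, muscle swelling translates the jaw — and
  the condylion landmarks — wholesale, which inflates the muscle
  scenario's apparent size effect and masks the constraining interaction
  between muscle and brain growth;
* **masticatory muscles** — two muscle systems per side.  The *elevator*
  pair (masseter/pterygoid/tongue-mass analogue) exactly fills a
  bone-bounded compartment between the cranial-base ceiling and the
  mandible-body floor, closed laterally, anteriorly and posteriorly by
  ~12 mm mandibular walls and meeting its twin at the midline.  Sealing
  this compartment is essential to the scenario comparisons: an osmotic
  tissue with any free surface equilibrates at zero pressure and cannot
  interact mechanically with the expanding brain, whereas the sealed
  compartment makes muscle growth pressurise the base and makes
  brain-driven basicranial descent compress the muscle.  The
  *temporalis-like* pair are ellipsoids (``muscle_semiaxes``) against the
  lateral vault wall.

The real neonatal skull is 2–3 mm thick; 7 mm is the thinnest shell the
default 7 mm voxel pitch resolves without holes.  A thicker shell is
stiffer, which the volume-targeting controller absorbs (section 3): the
growth-ramp multiplier needed to reach a given volume change is larger than
it would be for an anatomically thin skull, and we report multipliers, not
absolute ramps, as the calibrated quantity.  Default meshes are ~14 k
tetrahedra (~3 200 nodes), a deliberate desk-scale size chosen so a full
four-scenario analysis solves in minutes on one core; the published
workflow this emulates used over 200 k elements.

Voxel pitches above ~8 mm are not supported for simulation: the ~12 mm
compartment walls and condylar rami then collapse to single-cell chains
and the growth solve loses its load paths.

Boundaries are stair-stepped voxels, not smooth surfaces.  Volumes converge
as O(h²) (cell-centre classification), so the brain-domain volume is within
0.5 % of the analytic solid at the default pitch; landmark positions and
surface-distance summaries inherit ±h/2 quantisation, which is irrelevant
to the comparisons made here (they are all relative to the same mesh).

Eighteen basicranial–facial landmarks (8 midsagittal: Ans, Ba, Ds, Na, Op,
Pns, S, Ts; 5 bilateral pairs: Cd, Io, Lo, Mo, So) are defined
parametrically on the geometry (basal-opening rim, interior cranial base,
orbital rims of the facial block, mandibular condyles) and embedded in the
mesh as (tetrahedron, barycentric-weight) anchors.  Anchors deform with the
displacement field exactly linearly, so the simulation arm has no observer
(landmarking) noise by construction.  The node sets used as boundary
conditions are the two condylar patches lateral to the basal opening and a
single interior brain node (the spatial-anchor analogue).  A single-node
anchor is deliberate: any fully pinned tetrahedron inside a growing domain
becomes infeasible once the intracellular solid fraction ramps past 1
(section 2), and the brain is in any case tied to the skull at the whole
cavity interface.

## 2. Growth mechanics

Bone and mandible are compressible neo-Hookean solids
(σ = (μ/J)(B − I) + (λ ln J / J) I) with E = 300 MPa, ν = 0.3.  Brain and
muscles use the osmotic cell-growth material: the same neo-Hookean form for
the ground matrix (μ_s = λ_s = 10 kPa) plus an isotropic osmotic pressure

    π = RT · ( c_r / (J − φ_r) − c_e ),

where φ_r is the intracellular solid volume fraction per reference volume,
c_r the membrane-impermeant intracellular solute content, and c_e = 300 the
extracellular osmolarity.  Growth is driven by ramping (φ_r, c_r) linearly
in pseudo-time from the stress-free baseline (0.3, 210; note
c_r = c_e(1 − φ_r) makes J = 1 exactly stress free) toward the published
endpoints: (1.35, 945) for brain, (0.9, 630) for muscle.  RT defaults to
R·T at 310 K expressed in MPa per osmolarity unit (2.577 × 10⁻³), which
places the osmotic pressure scale (~0.77 MPa at c_e) in its physiological
ratio to the bone modulus; only this ratio matters to the mechanics and it
is exposed in the material config.  Setting RT = 1 in the same unit system
as E = 300 would make osmotic pressures comparable to the bone modulus
itself and no bounded skull could contain even a fraction of the ramp.

Discretisation: total-Lagrangian displacement formulation on linear
tetrahedra, full Newton with an analytically consistent tangent (verified
against finite differences to 10⁻⁵ relative), a backtracking line search
on the *total strain energy* (both materials are hyperelastic, so the
energy is the natural merit function and is far more robust than the
residual norm near soft-tissue instabilities such as the slight brain
herniation through the basal opening), a 25 mm trust-region cap on the
Newton increment, load stepping with automatic bisection (10 equal
pseudo-time steps by default, minimum step 1/160), and a direct sparse
solve (SuperLU) of each linearised system.  Convergence demands the free-dof residual norm
fall below 10⁻⁶ of the step's initial residual (plus a 10⁻⁸ absolute
floor).  No incompressibility treatment is needed: growth domains are
compressible by construction and bone at ν = 0.3 is far from locking; this
is a documented fidelity limitation of the linear-tet choice.

"Plastic" deformation means the retained deformed configuration of the
elastic solve — permanent shape change, not an elastoplastic constitutive
law; no unloading step is performed.

**Singularity regularisation.** The osmotic term diverges as J → φ_r.  In
a confined mesh, elements trapped near fixed boundaries cannot swell
arbitrarily, and once φ_r ramps past the locally achievable J the exact law
admits no equilibrium — a geometric artefact of conforming meshes with
point constraints, not of the physics being studied.  For J − φ_r below a
width ε = 0.1 the 1/(J − φ_r) factor therefore continues linearly (C¹
match at ε), so confined elements saturate at a large finite pressure
(~2 c_r RT/ε ≈ 45 MPa) instead of aborting the solve.  The public material
API keeps the strict behaviour (states with J ≤ φ_r raise a step-failure
signal); only the equilibrium solver evaluates the regularised branch.
Free-swelling states never enter the layer, so the patch-test oracle is
unaffected.

## 3. Volume-targeting controller

The published ramps define a growth direction; how much volume change they
produce depends on the surrounding structure.  The four scenarios are
therefore run through a controller that scales each growing tissue's
(φ_r, c_r) ramp endpoints by a scalar multiplier (interpolating along the
baseline→endpoint line) and iterates the achieved volume change onto the
target by a damped secant method.  Targets default to the "table1" preset
(+69 % brain, +32 % muscle — the changes actually analysed downstream); a
"measured" preset (+60 %, +35 % — the stereological measurements) is also
packaged.  Because the materials are hyperelastic, equilibrium is
path-independent; the controller marches the multiplier with warm-started
Newton solves (halving the multiplier increment on failure) rather than
repeating the pseudo-time continuation per candidate.  On the default head
the brain scenario converges near multiplier ≈ 1.11 and the muscle scenario
near ≈ 0.4 — the brain needs more than the published ramp because the
synthetic skull shell is thicker and stiffer than a real neonatal skull,
while the muscles, being largely unconfined, sit close to their
free-swelling response.  The combined Br+M scenario runs both systems at
the multipliers found individually.

## 4. Morphometrics

Generalized Procrustes analysis follows the conventions of the standard
geometric-morphometrics packages: centring, scaling to unit centroid size,
iterative rotation to the consensus (proper rotations only; SVD with
determinant correction) until the consensus changes by < 10⁻¹⁰ (max 100
iterations), then orthogonal projection onto the tangent space at the
consensus.  Centroid size is the square root of the summed squared
distances of landmarks from their centroid — the distance-from-centroid
convention; the phrase "distances between the landmarks" found in the
literature is ambiguous between this and the pairwise form (they differ by
√k), and the centroid convention is the field standard.  The consensus is
placed in a deterministic principal-axes frame (signs fixed by coordinate
skewness), which makes aligned coordinates invariant — not merely
equivariant — under rigid motions of the input sample.

Object symmetry: the sample is doubled with reflected (x → −x),
pair-relabelled copies and superimposed jointly; the consensus is then
rotated into its midsagittal frame and made exactly invariant under the
reflection/relabel operator Q, after which each aligned specimen splits as
symmetric = (a + Q a)/2 and asymmetric = (a − Q a)/2.  Because Q is an
orthogonal involution fixing the consensus, the two components are
orthogonal to machine precision and sum to the aligned original exactly.

Allometry: multivariate least squares of the symmetric shape coordinates
on log centroid size; the reported statistic is percent predicted
(100 · SS_fit / SS_total pooled over coordinates).  Significance comes from
permuting the covariate (default 10 000 permutations, seeded), with
p = (1 + #{permuted ≥ observed})/(1 + N) so p is never zero and ties count
against the hypothesis.  Residuals of this regression are the
non-allometric variation and are regressed on age in days; their percent
predicted is computed on the residual total sum of squares.  Form space
appends centred log CS as an extra coordinate.  Regression scores are
projections of centred specimens onto the unit regression vector.
Simulation results are landmarked automatically (mesh anchors) and
projected read-only into the fitted space: centred, unit-scaled, rotated to
the consensus, symmetrised with Q, tangent-projected, and scored with the
stored regression — the sample is never refitted.

## 5. Synthetic normative population

Each specimen is the symmetric mean configuration (the head mesh's
landmarks) plus

* an allometric effect b·v·(log CS − mean), along a fixed unit direction v
  that is symmetric and orthogonal to the similarity-transform directions;
* an age effect c·w·(age⊥), w ⊥ v, where age⊥ is the component of age
  orthogonal to designed log CS;
* isotropic landmarking noise (0.6 mm per coordinate), then scaling to the
  specimen's centroid size and an arbitrary rigid pose.

Defaults: n = 62, ages uniform on 0–120 days, centroid size spanning ~20 %
with corr(age, log CS) = 0.9, five specimens landmarked three times each
(replicates add noise only).  Carrying the age effect on age⊥ is forced by
the joint calibration targets: with strongly collinear age and size, an age
effect along raw (age − mean) pollutes the size regression several-fold
before the residual regression reaches its target, while with independent
age and size the residual target (0.8 %) would fall below the estimator's
null floor.  The orthogonal construction is also what "non-allometric age
effect" means operationally.

**Calibration.** The percent-predicted estimator is biased upward at finite
n (null expectation ≈ 100/(n − 1) for the size regression, shrunk by
1 − ρ² for the residual-on-age regression).  The effect scales b and c are
therefore solved against a Monte-Carlo oracle: 100 null populations run
through the actual GPA + symmetry + regression pipeline give per-replicate
sums of squares; closed-form amplitude equations on the Monte-Carlo average
give first estimates; two multiplicative bias-correction passes through the
full generator-plus-pipeline (80 replicates each) refine them.  The oracle
uses a fixed internal seed, so all population seeds share one calibration,
and requesting a fraction below the null floor raises an error naming the
floor.  With defaults the expected recoveries are 5 % (shape ~ log CS) and
0.8 % (residual ~ age).

What the generator does *not* emulate: measurement geometry of MRI
(resolution anisotropy, intensity-dependent landmark uncertainty),
population covariance structure beyond the two constructed effect
directions, asymmetry beyond isotropic noise, growth nonlinearity in age.
Passing recovery tests therefore demonstrates estimator correctness and
calibration, not robustness to real-data pathologies.

## 6. Volumetrics

The label-image pair renders brain and masseter as voxelised ellipsoids
(fixed axis ratios, semi-axes solved from the requested volumes) at 1 mm
spacing, with analytic ground truth: 400/640 cm³ brain and 3.0/4.05 cm³
masseter at the "14-day"/"90-day" ages, i.e. +60 % and +35 %.  The
Cavalieri estimator overlays a uniformly random-offset square grid on every
k-th section and counts voxel-centre hits: V̂ = ΣP · a_p · d.  Defaults use
a grid pitch of 4× the in-plane voxel pitch, tightened to 1/8 of the
structure's in-plane extent for small structures (keeping the coefficient
of error in the few-percent range), and a slice step sampling ≥ 10 sections
through the structure.  The estimator is unbiased over offsets (verified to
1 % against the analytic ellipsoid); the residual ~0.5 % bias visible in
the masseter change estimate is the voxelisation realisation of the 1 mm
grid, not a property of the estimator.

## 7. Surface comparison

Growth heatmap data are per-vertex exact closest-point distances from the
deformed bone surface back to the baseline surface, optionally signed by
the baseline's outward face normal (positive = outward growth).  A KD-tree
over target-triangle centroids provides an upper bound per vertex; every
triangle whose centroid sphere could beat that bound is then tested with an
exact point-triangle routine, so acceleration never changes the result
(verified against an all-triangles scan).  Vertices carry parametric region
labels (vault / face / base / other) from the generator, and regional mean
distances are first-class outputs — the brain-growth scenario shows larger
mean displacement over the vault than over the face, the qualitative
pattern the analysis is designed to exhibit.

## 8. Determinism and problem sizes

Every stage is a pure function of (config, seed): the master seed fans out
to named substreams (head, population, stereology offsets), generators are
bitwise reproducible, and the FE solve is deterministic to floating-point
reproducibility on one platform.  Default problem sizes — ~13 k-tet head
mesh, n = 62 populations, 50 stereology offsets, 10 000 permutations, 200
calibration/recovery replicates — are the package's desk-scale choices;
every one of them is a config field, and the statistical results scale as
expected when they are raised.

## 9. Known limitations

* Constructive voxel geometry: no sutures or fontanelles (the skull is a
  single spatially invariant material, as in the emulated workflow), no
  anatomical fidelity of muscle lines of action, stair-step boundaries.
* The skull shell is ~3× thicker than a real neonatal skull (mesh
  resolution), so absolute growth-ramp multipliers are not transferable;
  only volume-targeted comparisons are.
* Linear tetrahedra without incompressibility treatment; soft-tissue
  moduli are order-of-magnitude choices (the emulated workflow does not
  report them).
* The osmotic regularisation layer (section 2) caps local pressures in
  confined corners; states inside the layer are numerical, not physical.
* No contact, no CSF/meninges, no differential regional brain growth, no
  remeshing — growth beyond the modelled range would require all four.
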