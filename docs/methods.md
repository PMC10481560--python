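# Methods

This note documents the models, algorithms and numerical choices behind
`rectarc`, in the order the pipeline uses them, together with the defaults
that matter and the known limits of the desk-scale setting.

## Coordinate and grid conventions

All volumes live on axis-aligned grids with array axes (RL, AP, CC):
+RL = patient left, +AP = posterior, +CC = cranial.  World coordinates are
millimetres at voxel centres.  The default phantom grid is 2.5 mm
isotropic over 210 × 190 × 170 mm (84 × 76 × 68 voxels) — coarser than
the 2 mm CT slices of clinical practice, chosen so a full two-plan
optimization runs in minutes on one CPU.  Densities are relative electron
density (water = 1.0, air = 0.0); the clinical CT-number-to-density
conversion step therefore collapses to an identity mapping.

## Synthetic pelvic phantom

The generator is a pure function of a `PhantomSpec` (seed, spacing, body
semi-axes, tumour offset and scale, bladder overlap fraction).  Anatomy is
built from parameterised superellipsoids with a small seeded jitter
(centres ±3 mm, semi-axes ±5 %):

* **Body** — an extruded ellipse (92 × 55 mm semi-axes) with rounded
  CC ends; water-equivalent.
* **Gross tumour region** — a superellipsoid (52 × 50 × 46 mm semi-axes
  at `target_scale = 1`, exponent 4, so the lateral horns are wide) from
  which an anterior *compartment* lobe (the bladder/bowel space) is carved
  with 12.5 mm clearance.  Because the clearance exceeds the total
  in-plane margin growth (5 mm CTV + 5 mm PTV), the expanded target can
  never re-enter the compartment, which guarantees the horseshoe
  concavity (convex-hull volume ≈ 1.45 × the PTV volume at default).
* **Targets** — CTV = gross region expanded 5 mm AP/RL and 20 mm CC
  (nodal masks, when given, join unexpanded); PTV = CTV + 5 mm isotropic;
  both clipped strictly inside the body.  The default initial PTV is
  ≈ 670 cm³, inside the roughly 600–1400 cm³ range seen in locally advanced
  rectal cancer series;
  `target_scale` scales it linearly.
* **Bladder** — a 30 × 26 × 36 mm ellipsoid inside the compartment.
  `oar_overlap_fraction` slides it posteriorly by up to 40 mm into the
  anterior PTV face; at 0 it is confined to the compartment and provably
  disjoint from the PTV; the default 0.4 produces a ~9 cm³ overlap
  ("abutting/overlapping anteriorly").
* **Small bowel** — an anterior–superior ellipsoid (~150 cm³), minus the
  bladder.
* **Femoral heads** — 21 mm spheres at (±64, −16, −18) mm, carved to keep
  a 4 mm gap from the PTV, as real nodal targets pass medial to the hips.
  The carve flattens their medial face and leaves ≈ 20–25 cm³ per head —
  smaller than anatomical femoral heads; their dose metrics remain
  meaningful as percentages of structure volume.
* **Virtual couch** — a posterior slab (50 mm, density 0.3, 5 mm gap),
  inserted by the planner, not the generator.

Organs that would protrude through the body raise an explicit
infeasible-geometry error naming the structure.

## Structure algebra

Margin expansion is dilation by a piecewise-ellipsoidal structuring
element: a voxel joins the result iff
`Σᵢ (Δᵢ / mᵢ)² ≤ 1`, with the margin `mᵢ` picked per axis by the sign of
the displacement component (six independent directions; a zero margin
forces the component to zero).  The element is materialised explicitly
and applied by FFT convolution, which reproduces a brute-force distance
scan voxel for voxel (tested exactly on grids up to 40³).

Derived optimization ROIs (prefixed `z_`, flagged `derived`):
`z_Bladder_opt` and `z_SmallBowel_opt` (organ minus PTV), the
abdominal-direction shell `z_AnteriorShell` (PTV expanded 30 mm
anteriorly minus a 3 mm isotropic expansion, clipped to the body) and a
normal-tissue ring `z_NormalTissue` (PTV + 40 mm minus PTV + 2 mm).  The
anterior distances are configuration, not clinical constants; the shell
realises a bowel-bag-like control volume whatever the PTV shape.

## Dose engine

A deliberately simple, strictly linear primary-photon pencil-beam model —
chosen because every downstream algorithm (penalty descent, DVH, gamma,
sequencing) only needs linearity and a qualitatively correct depth/
penumbra structure, not a commercial-grade dose engine:

    dose/weight = output · exp(−μ·d_rad) · (SAD/w)² · G(Δu) · G(Δv)

with μ = 0.04 cm⁻¹ (10 MV-like), SAD = 1000 mm, Gaussian penumbra
σ = 3 mm truncated at 1.5 beamlet pitches (the 3 × 3 nearest beamlets),
beamlet pitch 5 mm, and 72 control points at 5° spacing.  Radiological
depth is a divergent-ray line integral, tabulated per control point on a
coarse beam's-eye-view lattice (2.5 mm steps along the ray) and
interpolated trilinearly per voxel.  No buildup, scatter or leaf
transmission is modelled, so depth dose decreases monotonically from the
surface.  The output factor is calibrated per phantom so 1 MU ≈ 0.01 Gy
at isocentre depth.  Dose is only computed inside the body; outside it is
identically zero.

The influence operator is stored matrix-free (per control point:
separable Gaussian factors folded with the depth/inverse-square factor);
`to_sparse()` materialises the identical explicit matrix for small
problems and tests.  The hot gather/scatter loops are JIT-compiled with
numba when available; a pure-numpy path produces the same numbers.

The collimator angle (355° for automated plans) rotates the BEV basis in
which leaf travel and leaf rows are defined; at 5° from zero its effect is
small but the code path is always exercised.

## Automated planning workflow

Stages, in order, each logged with wall time: ROI-name check → density
mapping (identity) → virtual couch → derived optimization ROIs →
isocentre at the PTV centroid, arc construction and output calibration →
influence matrix → objective construction → **2** optimization passes →
hotspot extraction → **3** hotspot-correction passes → PTV-coverage
constraint escalation → final optimization → leaf sequencing → plan
metrics; goals are evaluated once both plans (45 Gy initial on
PTV_initial, 5.4 Gy boost on PTV_boost) exist, organ-at-risk goals on the
voxelwise plan sum.  The boost plan is optimized independently, not
background-dose aware.  The pipeline is deterministic: identical inputs
give identical plans.

Objectives (one-sided quadratic penalties, each normalised by its ROI
voxel count):

* PTV: uniform at prescription (weight 3), minimum dose at 99.5 % of
  prescription (weight 60), maximum dose at 105 % of prescription
  (weight 15) — the cap sits below the clinical 110 % near-maximum goal
  on purpose.
* One dose fall-off objective per organ at risk referenced by the goal
  list, plus the anterior shell (weight 2) and the normal-tissue ring
  (weight 1): the penalty target ramps linearly from 100 % of
  prescription at the PTV-facing boundary down to 30 % at 20 mm, using a
  Euclidean distance transform from the PTV.
* A small fluence-roughness penalty (`smoothing_weight = 0.02`,
  normalised per beamlet) keeps the optimum deliverable by one aperture
  per control point.
* Hotspot correction adds a maximum-dose objective at prescription
  (weight 30) on the extracted hotspot voxels (≥ 1.05 × prescription
  inside the body; the threshold sits below the 110 % goal with
  headroom).

The solver is bound-constrained quasi-Newton descent (L-BFGS-B over
non-negative beamlet weights, warm-started between passes, 30 iterations
per pass by default); the objective trace at accepted iterates is
recorded and non-increasing, and an increase raises an error.  "Two
passes" and "three passes" are warm-started re-invocations with identical
(respectively hotspot-augmented) objectives.  Escalation multiplies the
PTV minimum-dose weight by 10 (marking it a constraint) for at most 5
rounds while D93 misses the 98 % goal; on the packaged phantom zero
rounds are needed (D93 ≈ 99.4 %).

## Leaf sequencing

Each control point receives one aperture: per fluence row, the longest
contiguous run of beamlets at ≥ 50 % of the row maximum; rows below 35 %
of the control point's overall maximum stay closed (one meterset per
control point would grossly overdose weakly-irradiated rows); the
meterset starts as the mean in-aperture fluence.  A refinement stage then
alternates a non-negative least-squares fit of the per-control-point
metersets to the fluence-optimal dose with greedy leaf-edge coordinate
descent (±1 beamlet moves, re-opening closed rows at their fluence peak)
on the squared dose error, with sparse cached beamlet columns (≤ 10
sweeps, early stop).  On the packaged phantom the sequenced plan
reproduces the fluence-optimal dose with a 3 %/2 mm gamma pass rate of
roughly 90 %: converting idealised fluence to a single aperture per
control point irreversibly loses in-row modulation, and the package
documents and checks this internal-consistency figure at ≥ 85 % rather
than claiming deliverable-equivalence.  Plan D93/D2, CI/HI and the goal
report are evaluated on the fluence-optimal dose; total MU and MCS come
from the sequenced plan.  No leaf-speed or dose-rate constraints are
modelled, which inflates achievable modulation and thus flattens the
realism of MCS comparisons.

## Evaluation and QA

* **DVH** — exact voxel counting into 0.05 Gy bins; Dx is the largest
  dose with cumulative fraction ≥ x %, linearly interpolated between bin
  edges (uniform-dose HI is therefore zero only up to one bin width); Vx
  is interpolated likewise and reported in % and cc.
* **CI/HI** — as defined above, from voxel counts and the DVH.  Clinical
  reports sometimes quote HI values near 0.7–0.8 alongside D2 ≈ 105 % and
  D98 ≈ 95 % of prescription, which is inconsistent with the
  `(D2 − D98)/D_prescription` definition (that gives ≈ 0.1); this package
  implements the definition literally, so its HI values live on the ~0.1
  scale.
* **Gamma** — global normalisation to the reference maximum, 10 %
  low-dose cutoff, search radius 3 × DTA sampled at DTA/5 with trilinear
  interpolation of the evaluated dose, evaluated lazily over
  distance-sorted offsets with an active set (exactly equal to the
  exhaustive search, tested).  The evaluated distribution may live on a
  shifted grid; it is interpolated once, inside the search.
* **Self-QA** — the plan's dose is recomputed with the ray-trace step
  halved on a half-voxel-shifted grid and gamma-compared at 3 %/2 mm.
  On the packaged phantom the pass rate is ≈ 99.8 %, against the 98 %
  robustness threshold used clinically.
* **MCS** — the VMAT form: per control point, aperture-area variability
  (summed openings over the per-pair arc maxima) × leaf-sequence
  variability (per bank, mean adjacent-leaf similarity relative to the
  bank's position range; 1.0 for a degenerate range), averaged over
  adjacent control-point pairs and weighted by relative meterset.
* **Wilcoxon** — midranks for ties, zero differences dropped; the
  two-sided p-value is exact for n ≤ 25 via the distribution of W⁺ over
  all 2ⁿ sign assignments (dynamic programming over doubled ranks), and a
  tie-corrected normal approximation with continuity correction beyond.

## What the phantom does and does not show

Passing goals on the synthetic phantom demonstrates that the *workflow*
(structure derivation, objective construction, staged optimization,
escalation, evaluation) functions and that the geometry class it assumes
(concave target wrapping anterior organs) is handled.  It does not
demonstrate clinical dose accuracy: the phantom is water-equivalent (no
bone or gas), the dose model omits scatter and buildup, organs are
smooth superellipsoids without inter-patient variability, and the
femoral heads are smaller than anatomical ones.  Cohort-level dosimetric
comparison on patient data is out of scope; the paired-comparison tooling
(`rectarc compare`) operates on any user-supplied per-case metric tables.
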