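# Methods

`crtlead` is a virtual-trial engine for quadripolar cardiac
resynchronization therapy (CRT) leads.  It answers, on synthetic
biventricular anatomies, the questions a lead-design trial would ask: how
much does left-ventricular (LV) pacing from each 1- or 2-electrode
configuration of an 8-position epicardial array improve electrical
synchrony over right-ventricular (RV) pacing alone, which 4-electrode lead
design covers the most patients' optima, and how robust are those answers
to the conduction-model assumptions.

## Activation model

Ventricular activation is modelled with the anisotropic eikonal equation

    sqrt( grad(T)^T V grad(T) ) = 1,

where `T(x)` is the activation time (ms) and `V(x)` the squared
conduction-velocity tensor ((mm/ms)^2; mm/ms is numerically m/s).  Working
myocardium is transversely isotropic about the local fibre direction `f`:

    V = cv_f^2 f f^T + (k_xf cv_f)^2 (I - f f^T),

with `cv_f = 0.5 mm/ms` along the fibre and cross-fibre ratio
`k_xf = 0.6`.  A fast endocardial conduction (FEC) layer, one element
thick, stands in for the Purkinje system: endocardium-adjacent elements in
the apical fraction `fec_extent = 0.33` of the apicobasal coordinate (both
ventricles by default; config-exposed) become isotropic with speed
`k_fec * cv_f`, `k_fec = 5`.  An optional first-order scar rule blocks
conduction in LV elements whose wall thickness falls below a threshold
(5 or 6 mm in the sensitivity grid); scar wins over FEC.

The model deliberately stops at first arrival: no membrane kinetics,
repolarization or ECG synthesis.  QRS duration is approximated by the total
activation time (TAT).

### Solver

The solver iterates locally exact tetrahedron updates to a fixed point:
the candidate arrival at a node through the opposite face of each incident
tetrahedron minimizes `T(p) + sqrt((x_v - p)^T V^{-1} (x_v - p))` over the
face (closed form via the stationarity condition, with edge and vertex
fallbacks when the face minimizer is infeasible).  Iteration is
Gauss-Jacobi restricted to an active set, seeded with an edge-graph
Dijkstra upper bound so only the metrication corrections remain; the
per-(mesh, field) coefficients are precomputed once and reused across
pacing sources.  Convergence tolerance is 1e-6 ms.

Two consequences worth knowing:

- **Multi-source solves are exact minima.**  First arrival from several
  simultaneous stimuli equals the pointwise minimum of the single-stimulus
  fields, so multi-source requests are assembled that way (a joint sweep
  would suffer O(h) crosstalk where fronts meet).  Single-source fields
  are cached per node; a full 36-configuration campaign on one heart costs
  one solve per electrode plus one for the RV lead.
- **The Dijkstra oracle is a bound, not a limit.**  Shortest paths on the
  edge graph (weight `sqrt(e^T mean(V)^{-1} e)`) always upper-bound the
  eikonal solution, but on structured meshes they keep an O(1) *relative*
  metrication excess in directions not representable by lattice edges;
  the bound is tight (and tested tight) only along edge-aligned rays.

Verification: travel times on a 1 mm cube match `distance/speed`
(isotropic) and the ellipsoidal closed form `sqrt(e^T V^{-1} e)`
(anisotropic) within 5% away from the source, and errors shrink under
refinement.

## Synthetic anatomy

The published study used CT-derived cohorts (24 heart-failure patients,
20 healthy subjects as reverse-remodelled proxies).  Those meshes are not
redistributable, so the generator builds idealized stand-ins and the
pipeline also accepts external meshes (ASCII VTU or CARP `.pts/.elem/.lon`
with surface labels).

Geometry: the LV is a truncated prolate-ellipsoid shell (endocardial
semi-axes `lv_endo_radius`, `lv_long_axis`; wall offset along the surface
normal so thickness is exact); the RV is a thinner crescent shell offset
outward across a lateral sector of the LV epicardium, leaving an RV cavity
gap that closes at the crescent rim.  The construction is a structured
apicobasal x circumferential x transmural lattice split into tetrahedra by
the Kuhn subdivision (face-consistent, no external mesh generator,
bitwise deterministic).  Because the wall is a normal offset, the basal
truncation surface is the ruled annulus between the endo and epi base
rings rather than an exactly planar cut; labels and invariants are
unaffected.  The LV wall thins linearly toward the apex
(`apex_thinning = 0.25`), giving the thickness-based scar rule something
real to act on.

Cohort defaults (chosen as plausible magnitudes, not fitted claims): HF
mean LV cavity ~ 180 mL with 8 mm wall; RR ~ 120 mL with 10 mm wall;
10% lognormal coefficient of variation on all lengths; per-subject seeds
spawn deterministically from the cohort seed.  The LV cavity volume of a
generated mesh matches the closed-form truncated-ellipsoid volume within
2% at 2 mm edge length.

Fibres follow a rule-based transmural helix: in each element the frame
(circumferential, longitudinal, transmural) comes from the gradients of
the coordinate fields, and the fibre lies in the wall-tangent plane at
helix angle varying linearly from +60 deg (endo) to -60 deg (epi) in the
transmural coordinate.  The full Laplace-Dirichlet rule set (septal
special-casing, sheet directions) is out of scope.

What the synthetic cohort does *not* emulate: real septal geometry and
outflow tracts, trabeculation, regional wall-motion-derived thinning,
valve planes, and the anatomical variability of CT cohorts.  Synthetic
baseline TATs are therefore longer (~230-270 ms) than the published
per-patient values (~138-167 ms), and mean AT090 reductions larger
(~17-27% vs ~11-13%).  Passing tests show the machinery is correct and
the qualitative structure (HF larger and slower than RR, pacing never
hurts, pair >= single, anatomy-dominated variance) is reproduced — not
that the published cohort numbers are.

## Coordinates

Apicobasal `z` and transmural `rho` come from linear-FEM Laplace solves
(1e-9 relative residual, sparse direct).  `z`: base = 1, apex cap = 0 on
the biventricular domain.  The raw harmonic field crowds logarithmically
near the near-point apex (a third of the *field* would be only ~13% of
the *height*), so `z` is re-labelled monotonically by the mean normalized
axial height of its level sets: surfaces keep their Laplace smoothness,
but `z = 0.33` means a third of the way up — which is what the FEC band
("bottom third") and the basal electrode ("80% of the apicobasal
distance") require.  `rho` is solved per ventricle (LV: endocardium 0,
epicardium and septal RV-endocardial surface 1; RV free wall: endo 0,
epi 1).  At the crescent rim a handful of junction nodes lie on both an
endocardial and an epicardial-labelled face; the endocardial value wins
there.  `phi` is the angle about the long axis (node-centroid to
base-centroid direction), zero at the anterior LV free wall, increasing
toward the lateral wall.

The AHA-17 map is assigned from `(z, phi)` bands: cap `z <= 0.15`, apical
to 0.45, mid to 0.72, basal above; sectors centred on the standard segment
angles.  The bands and the rotational origin are conventions (exposed in
`coordinates.py`), since no canonical cut-offs exist for UVC-derived maps.

LV wall thickness is measured per element by casting rays from the
centroid along the +/- transmural gradient to the endocardial and outer
(epicardial or septal right-endocardial) surfaces (vectorized
Moller-Trumbore with a KD-tree prefilter; nearest-surface-point fallback
for the rare miss through the base).

## Leads and the campaign

Five vein tracks run down the LV free wall at fixed rotational angles
anchored to the basal AHA segments: IN (border 4/5, 150 deg), IL (centre
5, 120 deg), LA (border 5/6, 90 deg), AL (centre 6, 60 deg), AN (border
6/1, 30 deg).  Each track is the exact slice of the epicardial surface by
the constant-phi half plane, ordered base-to-apex; electrodes `a`..`h`
sit at 0, 7.5, ..., 52.5 mm of arc from the `z = 0.8` start point, each
snapped to the nearest epicardial mesh node (ties to the lowest index).
Snapping quantizes positions by about one ring spacing at coarse
resolution.  The RV electrode is the RV endocardial node of minimal `z`
(apex) or the septal node nearest `z = 0.5` (sensitivity scenario).

A pacing configuration stimulates 1 or 2 LV electrodes simultaneously
with the RV electrode, all at onset 0 (36 unique stimulus sets per vein);
a lead design is any 4 of the 8 positions (70 designs, each admitting 10
configurations).  The campaign stores per-record TAT and AT090 (time to
activate 90% of the active biventricular volume; element time = nodal
mean, volume-weighted scan) and their reductions versus the RV-only
baseline, in ms and % of baseline.  Design-level responses are table
lookups (best admissible configuration), identical to simulating each
design at roughly a third of the cost.  An LV electrode snapped onto a
scar-deactivated element does not capture: its stimulus simply
contributes no activation (the RV lead keeps every record well-defined).

## Optimization, clustering, statistics

Patient-based optimum: argmax of the AT090 percent reduction over
configurations (and veins), ties to the lexicographically smallest
configuration name, then the conventional vein order.  Cohort-based
selection collects each subject's best configuration at their best vein
and finds a minimum-cardinality set of designs containing all of them by
exhaustive search over cover sizes 1, 2, 3, ... (70 candidate designs and
at most 36 targets keep this trivial); ties resolve lexicographically,
and a greedy cover exists as a cross-check only.  An optional tolerance
treats near-ties as equally optimal (default 0).  The primary design is
the single design covering the most subjects.

Response matrices are clustered with Ward's minimum-variance criterion in
its distance-input form (ward.D2 / Murtagh-Legendre) on Euclidean
distances, via `scipy.cluster.hierarchy.linkage(method="ward")`; the test
suite pins the variant against a hand-rolled Lance-Williams recurrence.
Flat labels default to 4 clusters.

Statistics: one-sided Wilcoxon signed-rank for paired reductions
(H0 symmetric about 0, zeros dropped; exact null for n <= 25 without
ties), Mann-Whitney U for unpaired strategy comparisons (exact for
n_x * n_y <= 400 without ties), Bonferroni over each family of pairwise
comparisons, significance at p < 0.01.  Effect sizes (median reductions)
are always reported alongside p-values, since with thousands of simulated
records p-values alone are nearly meaningless.

## Sensitivity analysis

One-at-a-time grid (11 scenarios): `fec_extent` {0.70, 1.00}, `cv_fibre`
{0.07, 0.8} mm/ms, `k_xf` {0.29, 1.0}, `k_fec` {7, 10}, RV lead at the
septal mid-wall, and scar thresholds {5, 6} mm.  Each scenario re-runs
the full campaign and design selection, reporting the primary design,
cover size and mean reductions, so the sensitivity of the conclusions is
what is measured.  Guaranteed monotonicities (activation times
non-increasing in `k_fec` and `cv_fibre`; nested scar thresholds give
nested activation-time orderings) are asserted per record in the tests.
Note that a global `cv_fibre` change rescales *all* speeds (FEC
included), so percent reductions are invariant to it — only absolute
times move.

## Problem sizes and numerical choices

Default test/acceptance sizes are deliberately small: campaign meshes use
5.5 mm target edges (~10-12k tetrahedra, ~1 s per source solve after
setup), the solver-verification cube 1 mm edges, and the demonstration
cohorts 2 HF + 2 RR subjects with 2 veins.  All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; identical
configurations reproduce response tables bitwise.  Degenerate inputs are
rejected loudly (infeasible geometry, missing surface labels, sources on
inactive tissue, empty samples); numerical over/undershoot of the
coordinate fields is clamped at 1e-6.

## Known limitations

- Idealized anatomy (see above); absolute activation times and reduction
  magnitudes are not comparable to CT-cohort values.
- The eikonal model ignores wavefront curvature, source-sink mismatch and
  repolarization; TAT is a crude QRS surrogate.
- Vein tracks are idealized constant-angle lines, not coronary-sinus
  anatomy; implantation and phrenic-nerve constraints are out of scope.
- The electrode "does not capture on scar" policy is a modelling choice;
  real devices would reposition or reprogram.
- The published count "70 combinations" of 1- and 2-electrode choices is
  arithmetically C(8,4): the package treats 70 as the quadripolar design
  count and C(8,1)+C(8,2) = 36 as the unique stimulus-set count, and
  evaluates designs over their admissible configurations.
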