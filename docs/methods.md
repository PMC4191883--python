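# Methods

This note documents the models, parameter choices and numerical
decisions behind `statemap`, and what the synthetic-data tests do and
do not establish about real trajectories.

## Descriptors

**Interhelical distances.** The three state-discriminating descriptors
are Euclidean distances between segment centers of mass: TM1b–TM10ec
and TM6a–TM10ec (EC vestibule) and TM1a–TM6b (IC vestibule), with the
segment definitions TM1a R11–A22, TM1b L25–A35, TM6a G242–L255, TM6b
F259–Y268, TM10ec K398–V412. The default CoM is the unweighted mean
over Cα atoms, which is the convention behind the shipped state
templates; a mass-weighted CoM over all selected atoms is available
(`weighting="mass"`) for analyses phrased in terms of residue mass
centers. Both are invariant under rigid motion of the model, which the
property tests verify with random rotations.

**Helix tilt.** The TM1a orientation is the first principal axis of
the segment's Cα cloud, signed so the N→C direction is positive, and
reported as the angle to the membrane normal (+z of the input frame;
the package performs no automatic membrane alignment). An end-to-end
vector convention would also be defensible; the principal axis was
chosen because it is less sensitive to terminal-residue noise. Note
that for helices whose length is not an integral number of turns the
principal axis deviates from the geometric axis by a degree or two;
tilt *differences* between conformers of the same segment are accurate
to well under 1°. A tilt relative to a stored reference axis (e.g. the
OF-closed pose) can be computed by passing that axis as the reference.

**Gates.** Gate distances are minima over cross pairs of partner
atoms: side-chain N × carboxylate O for salt bridges, donor/acceptor
heavy atoms for H-bonds, cation N to ring centroid for cation-π, and a
generic minimum heavy-atom distance for aromatic contacts. Closed-state
cutoffs are not part of the state definitions in the source analysis
and are field-standard defaults here: 4.0 Å (salt bridge, min N–O),
3.5 Å (H-bond, heavy atoms), 6.0 Å (cation-π), 5.0 Å (aromatic
contact). All are editable in the YAML config; "closed" is
distance ≤ cutoff, inclusive.

**Superposition.** RMSD uses the Kabsch SVD solution with a
determinant correction against improper rotations; the test oracle is
Horn's quaternion method, implemented independently in the tests.

## Hydration, cavity and pore metrics

Vestibule regions are spheres (default radius 8 Å) centered on the
midpoint of segment CoMs — EC on TM1b/TM10ec, IC on TM1a/TM6b — so
the regions track the conformer. These anchors are a modelling choice:
published hydration figures for this system delineate the vestibules
pictorially, not numerically.

Cavity volume is a POVME-style grid flood fill: a grid (default
1.0 Å spacing) spans the atom bounding box plus a 2 Å margin; a point
is occluded within vdW + probe (Bondi radii, 1.4 Å probe) of any atom;
the cavity is the set of unoccluded points connected to the
binding-site seed, with 6-neighbor connectivity by default
(conservative against corner leaks; 26 available), and volume =
count × spacing³. The result records whether the cavity reaches the
grid boundary, which distinguishes closed pockets from open funnels.

The pore profile follows the HOLE idea: at each z slice the radius of
the largest sphere centered in-plane that touches no atom,
r(c) = min_i(|c − r_i| − vdW_i), maximized over (x, y). The
maximization is multi-start Nelder–Mead seeded from the previous
slice's center plus eight perimeter starts (2 Å ring) — an
approximation to HOLE's simulated annealing that is exact on the
smooth channel phantoms used in the tests and adequate for
funnel-shaped vestibules; highly tortuous side channels would warrant
the full annealing search. Radii are capped at 15 Å so profiles
terminate in open vestibules; a fully blocked slice reports radius 0
with a blocked flag.

## Collective motions

The ANM Hessian uses all Cα atoms, a 15 Å pairwise cutoff and a
uniform force constant of 1 (arbitrary units — only eigenvalue ratios
and mode shapes are meaningful). A connected network has exactly six
near-zero eigenvalues (rigid-body null space); the implementation
refuses disconnected networks, listing the component sizes. The test
oracle is a finite-difference Hessian of the elastic-network energy,
so the analytic block assembly is checked against the potential it
claims to represent, not against itself.

PCA superposes frames onto their evolving mean (two refinement
passes — the fitting reference is not specified in the source
analysis), diagonalises the 3N coordinate covariance, and reports
variance fractions λ_i/Σλ. Mode projections re-fit each frame to the
stored mean before taking the dot product. Reported trajectory-derived
variance fractions from the original study (e.g. a first mode carrying
28% of the dynamics) depend on trajectories that were never deposited;
the package reproduces the *format* and contracts of that analysis,
verified on ensembles with imposed covariance.

## Biased-sampling toys

The aMD boost ΔV = (E − V)²/(α + E − V) applies when V < E. The
boosted surface V* = V + ΔV is C¹ at V = E, bounded by E below
threshold, and strictly monotone in V; the boosted force is the
unbiased force scaled by (α/(α + E − V))². Reweighting uses
w ∝ exp(ΔV/k_BT) with max-shifting against overflow, and the
statistical error of reweighted observables is estimated by block
bootstrap (50 blocks), which preserves serial correlation. With
k_B = 0.0019872041 kcal/(mol·K) and T = 310 K by default, the study's
dihedral-boost parameters E = 18,600 and α = 210 kcal/mol give
ΔV(E) = 0, ΔV(E − α) = α/2 = 105 kcal/mol, reproduced exactly. The
1-D toy applies the threshold to the total (single-term) dihedral
energy; whether a multi-torsion threshold is total or per-torsion is
immaterial here and left to the caller in any extension.

The tMD restraint is ½(k/N)(RMSD(t) − RMSD*(t))² with
RMSD*(t) = RMSD(0)·(1 − t/duration), k = 200 kcal/(mol·Å²) by default.
The restraint is two-sided (force changes sign ahead of schedule). The
per-atom force uses the analytic RMSD gradient after Kabsch
superposition — the target is rotated onto the instantaneous structure
each step, and the rotation's own derivative vanishes at the optimum —
verified against finite differences in the tests.

Both toys use overdamped (Brownian) Langevin dynamics: Euler–Maruyama
with x ← x + (dt/γ)F + √(2k_BT dt/γ)ξ. The tMD toy runs a 10-bead
chain held together by a soft elastic network (springs between pairs
within 6 Å of the start geometry, k_net = 0.05) so that the steering
term dominates; at T = 30 K and 4,000 steps of dt = 0.01 the final
RMSD to the target is ≈ 0.3 Å. These are toy-scale settings chosen for
clean convergence of the formula contracts; they make no claim about
all-atom steering. An optional constant z-force reproduces the role of
a weak membrane-normal external potential.

## Six-state classification

The source analysis distinguishes states by descriptive criteria
(hydration, packing, gate status), not an algorithm. The classifier
here is the minimal probabilistic formalization using only the printed
numbers: each state is an independent-normal template over the three
interhelical distances (means and SDs from the per-state simulation
statistics), gated by hard constraints on the substrate flag and gate
booleans. A frame is scored only against states whose constraints it
satisfies; the winner maximizes the Gaussian log-likelihood, and a
frame satisfying no state's constraints is labelled `unassigned` with
a nearest-state annotation. Hard-constraint choices:

* OFo requires both EC gates open; every other state requires at least
  one EC gate closed.
* The IC gate R5-D369 (with E6-R375) is closed in OF states and the
  apo-occluded state, open in the holo-occluded and IF states.
* holo-occluded additionally requires the W8-Y268 contact closed
  (it is the last IC barrier in that state); IFo* requires it open.
* Starred states differ from their unstarred twins only by the
  substrate-bound flag, since the published packing statistics pool
  them.

TM1a tilt and water counts are carried in the descriptor frame and
reported, but do not enter the default score: no published calibration
(means/SDs) exists for them, and adding uncalibrated soft terms would
degrade the parts that are calibrated.

Label series are smoothed by a 5-frame centered majority vote (ties
keep the current label) before run-length encoding; the analysis
targets persistent states, not single-frame flicker. Release detection
reports the first frame whose ligand CoM crosses the z threshold and
stays beyond it for 10 frames.

Scale consistency: multiplying all template SDs by a common factor
leaves each within-constraint-class argmax unchanged, which the tests
assert; hard constraints are unaffected by SD scaling.

## Synthetic-data generator

The generator emulates exactly the statistical structure the analysis
consumes: five ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å
radius) with the native residue numbering, placed so the three
descriptor distances equal draws from each state's Gaussian template;
single-atom gate "side chains" at 3 Å (closed) or 10 Å (open)
separation; water oxygens in the vestibule spheres with per-state
counts (OF: EC hydrated/IC dry; IF: reversed; occluded: both minimal,
following the published hydration patterns); TM1a tilt per state (5°
OF-like, 10° occluded, 45° IF-like, consistent with the reported
excursions of up to ~40° from the OF pose); and substrate/Na⁺ markers
whose z positions follow scripted release ramps into the IC bulk.
Because the three target distances constrain disjoint segment pairs,
CoM placement is solved directly (EC layer / IC layer construction)
with no infeasible configurations, so no resampling is needed. A fixed
water budget (unused waters parked in a distant reservoir layer) keeps
the topology constant across a multi-state trajectory; state
boundaries are joined by 3-frame linear interpolation labelled with
the destination state.

What passing these tests shows: the descriptor, classification,
transition and release machinery is correct on inputs with the assumed
statistics. What it does not show: anything about force fields,
sampling adequacy, membrane alignment, or descriptor behaviour on real
side-chain geometry — the generator has ideal helices, pointlike gate
atoms and uniform vestibule water, and real trajectories violate the
independent-normal descriptor model at boundaries between states.

## Problem sizes and determinism

Default verification sizes: 500 draws per state for classifier
recovery; a 165-frame six-state cycle (25 frames/state); a 5,000-atom
hollow-shell phantom for the cavity check; a 21-ring cylinder for the
pore check; 10⁵ Langevin steps for the aMD toy and 4 × 10³ for the tMD
toy; 30-residue helices for mode checks. Every stochastic operation
takes an explicit seed and is bit-reproducible given it; the pipeline
manifest records a config hash and the SHA-256 of the descriptor
table, and re-running with the same inputs reproduces it exactly.

## Known limitations

* PDB is the only structure format (multi-model PDB for ensembles);
  no DCD/XTC, mmCIF, or topology formats. Residue insertion codes are
  rejected explicitly rather than renumbered.
* Crystal-structure descriptor checks use deposited numbering
  unchanged; structures with engineered numbering shifts need a custom
  segment config.
* The pore search is a local optimizer; pathological multi-channel
  slices may report a local rather than global maximum.
* The classifier's gate cutoffs and the vestibule region anchors are
  assumptions (flagged in the config), not published calibrations.
* The biased-sampling integrators are overdamped toys; no inertial
  thermostat fidelity is claimed.
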