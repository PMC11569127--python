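# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `loopstate`, in the order data flows through the
package.

## Coordinate model and I/O

Coordinates are Å, times ns.  Trajectories are stored as one shared
topology plus an `(n_frames, n_atoms, 3)` array; frames of one trajectory
therefore share atom ordering by construction.  PDB is the interchange
format (multi-model PDB for trajectories, one MODEL block per frame),
parsed and written through `biotite`; of alternate-location records, the
first (conventionally "A" or blank) is kept.  Multi-model files read as a
single structure yield model 1.  Frame times come from the stride
(default 0.2 ns/frame, the cadence at which production snapshots are
typically saved) since PDB carries none.  Binary trajectory formats are
not read directly; converting to multi-model PDB upstream keeps the
desk-scale data path fully text-based.

Metrics never hard-code residue numbers.  A `LandmarkMap` binds *role*
names to chain/residue/atom: anchors `icl2_marker_tip` (Y114:OH in FFAR1),
`icl2_marker_base` (L112:CG), `tm2_ref` (T39:CB), `tm5_probe` (CA 190),
`tm4_lower`/`tm4_upper` (CA 130/141), `g_loop_start`/`g_loop_end`
(Gα CA 504/508), and ranges `icl2` (residues 110–118 in FFAR1),
`align_set` (the TM1–TM4 CA set), `galpha_h5` (Gα 519–530).  The map also
carries a Ballesteros–Weinstein table so analyses can be specified in
generic GPCR numbering.  Receptor and G protein are distinguished by
chain id.  G-protein residue numbers follow the construct at hand and
must be user-supplied for real complexes.  Structures are assumed already
oriented with the membrane normal along z, extracellular side +z (the OPM
convention); the package does not compute membrane orientation.

## The ICL2 angle

The frame is superposed onto a reference on the `align_set` CA atoms by
closed-form least-squares rigid superposition (Kabsch via SVD, with the
determinant correction that excludes reflections; inputs of fewer than
three or near-collinear points are rejected).  This placement leaves the
loop's helix axis approximately along x, so its rotation appears as an
angle in the z,y plane: with **v** the vector from the marker base to the
marker tip, `a_raw = atan2(v_z, v_y)` in degrees, wrapped to (−180, 180].
`a_rel` subtracts the reference structure's own raw angle, so traces read
0° at the crystal-like conformation.

Two conventions are fixed here and configurable: the marker vector points
base → tip (flipping it shifts `a_raw` by 180°), and classifier
thresholds apply to `a_raw`, not `a_rel` — the crystal conformation
itself must score PR, which it does on the raw angle (the toy receptor's
crystal-like frame sits at +80°) but could not on the zeroed one.

Because the angle is read in the reference's z,y *lab* plane, it is exact
under the transforms that preserve that plane (translations, rotations
about x: `a_raw` co-rotates, `a_rel` is invariant) but not under
arbitrary joint rigid motions of frame and reference.  The axis-fitted
rotation angle closes that gap: it fits the helix axis to the reference
loop CAs, aligns the frame on `align_set`, and reports the circular mean
of the two markers' azimuth changes about the axis.  It is invariant
under arbitrary joint rigid motions and agrees with the plane projection
to within a few degrees whenever the loop axis lies near x; both are
computed so each can validate the other.

The helix-axis fit itself uses the running centers
`c_i = mean(CA_i … CA_{i+3})`, which cancel most helical wobble; the axis
is the principal (SVD) direction of those centers, oriented from lower to
higher residue numbers, and needs ≥ 5 consecutive residues.  The fit is
parameter-free and rotation-equivariant to well under a degree on ideal
geometry, which is why it is preferred over heavier helix-fitting schemes
for a nine-residue loop.

## Helicity and the three-state classifier

A frame is *helical* when either branch fires: (i) at least `hbond_min`
(default 3) backbone O(i)···N(i+4) hydrogen bonds inside the loop range,
or (ii) loop backbone (N, CA, C, O) RMSD below `rmsd_max` (default 2 Å)
after superposing that selection onto a reference whose loop is folded.
The two-branch rule tolerates transient fraying of individual hydrogen
bonds (an intact nine-residue loop carries five candidate i,i+4 bonds;
real initial helices often hold only four) while the RMSD branch catches
frames whose carbonyls tilt without the fold changing.

The classifier then assigns, with defaults
`a_low, a_high = 45°, 120°`, `d_high = 13 Å`,
`d_low(a) = 10 − a/20 Å`:

* DISORDERED iff not helical;
* PR if helical, `a_low < a_raw < a_high`, and `d_low(a_raw) < d < d_high`;
* NR otherwise.

The sloped lower distance bound tracks the tip's geometry: as the loop
rotates to larger angles the tip sits slightly closer to TM2, so a fixed
lower bound would clip genuine PR frames.  The classifier is pure
arithmetic on `(a, d, helical)` and is property-tested for exact
agreement with a literal evaluation of the inequalities on a
10,000-point grid.

## TM5 shift and G-protein metrics

`tm5_vertical_shift` projects the TM5 probe CA onto the line through the
TM4 lower/upper CAs (signed, unclamped projection), with the segment
direction oriented so it points extracellular (+z); the sign convention
makes positive values an upward TM5 shift.  `reference_s` subtracts a
baseline — the agonist-free crystal value when analyzing FFAR1, zero
otherwise — and `crystal_shift_report` differences two structures
directly.  `helix5_displacement` superposes the frame on the receptor
`align_set` only and reports the RMSD of the Gα helix-5 CAs without
refitting, so the number is displacement of the G protein relative to the
receptor.  CA pair distances and the Gα β6–α5 loop end-to-end distance
are plain Euclidean distances.

## Hydrogen bonds and water bridges

Detection is geometric: donor–acceptor heavy-atom distance
≤ 3.5 Å and, when the donor carries hydrogens, a D–H···A angle ≥ 110°
(180° = linear); both cutoffs are configurable since "standard geometric
criteria" vary by a few tenths of an Å and tens of degrees across common
tools.  On structures without hydrogens the distance criterion alone
applies, making heavy-atom detection a strict superset of hydrogen-aware
detection at equal cutoff; `add_amide_hydrogens` places backbone amide
hydrogens by trigonal geometry when hydrogen-aware counting is wanted on
crystal structures.  Donor/acceptor typing is by residue template
(backbone N donor, backbone O acceptor, hydroxyls both, carboxylate O
acceptor, water O both) with an element fallback for ligands.  A water
bridge joins two solute atoms each hydrogen-bonded (either role) to the
same single water in one frame; two-water chains are not counted, the
conservative reading when bridge definitions are unspecified.  Inputs are
assumed re-imaged/whole; no periodic-boundary handling is done.

Interaction frequency for an atom pair is qualifying frames (direct OR
water-mediated) divided by frames passing the frame filter, computed per
replicate; the filter defaults to folded-loop frames only (RMSD branch),
because comparing hydrogen-bond occupancy between conditions is only
meaningful on conformations that have the loop's donors and acceptors in
place.  Replicates with no frame passing the filter are excluded with a
warning rather than poisoning the mean.

## Replicate statistics

The sampling unit is the independent simulation.  Condition summaries are
means of per-replicate time-averages with a 68% confidence interval of
one standard error of the mean (the 1-sigma convention for "68% CI"); a
percentile-bootstrap alternative is available.  Comparisons use the
two-sided Mann–Whitney U test on the per-replicate values, with midranks
for ties; for pooled sizes ≤ 14 the p-value is exact by complete
enumeration of all label assignments (two-sided via deviation of U from
its null mean, which reduces to the textbook definition and is verified
against an independent pair-count enumeration), larger samples use the
normal approximation with tie and continuity corrections.  Frames within
a replicate are autocorrelated, which is precisely why per-frame counts
are never fed to the test — only one number per replicate.  No
multiple-testing adjustment is applied across metrics; p-values are
reported raw.

## Dihedral PCA

Backbone φ (C′₋₁–N–CA–C′) and ψ (N–CA–C′–N₊₁) are computed by the
standard projected-vectors torsion formula (IUPAC sign convention) and
encoded as (sin, cos) pairs — 4 features per residue — removing the
±180° wrap discontinuity.  With the helical filter on, only frames
passing the RMSD branch of the helicity rule enter the matrix.  PCA is a
mean-centered covariance eigendecomposition with eigenvalues clipped at
zero, components sorted by explained variance, and a deterministic sign
convention (largest-magnitude loading positive).  The residue range can
be given numerically, as a named range, or as a Ballesteros–Weinstein
code pair resolved through the landmark map.

## The synthetic generator

The toy receptor is four parallel TM helix stubs spanning z = ±15 Å (the
alignment set, residues 5–24, 30–49, 85–104, 124–143), a TM5 stub
carrying the shift anchors, and a 17-residue loop helix along x at
z = −16 Å whose central 9 residues (110–118) are the ICL2 analogue, with
two flanking residues beyond the dihedral range so terminal φ/ψ are
defined.  Marker pseudo-atoms named CG (residue 112, radius 5 Å) and OH
(residue 114, radius 9 Å) sit at azimuths −100° and +80° off the loop
axis, so the base-frame angle is exactly +80° and the marker vector's
transverse length is 14 Å — large enough that 0.3 Å coordinate noise
propagates to only ≈ 1.8° RMS of angle noise.  The TM2 reference atom is
placed exactly 10.2 Å from the resting tip, on the ray pointing away from
where a −40° rotation carries the tip, so the NR state lands at
a ≈ 40°, d ≈ 16.3 Å — outside the PR box on both axes, which is what
makes per-frame classification reliable under noise.  An optional Gα
chain supplies helix-5 and β6–α5-loop CAs (end-to-end 7.0 Å by
construction).

Helix backbones are parametric: CA atoms exactly on a cylinder (defaults
rise 1.5 Å, twist 100°, radius 2.3 Å) with N, C, O at cylindrical offsets
fitted once to an ideal (φ, ψ) = (−57°, −47°) α-helix built from standard
internal coordinates; the result hydrogen-bonds every i,i+4 O···N pair at
2.86 Å and reads back α-helical dihedrals.  A second, torsion-driven
builder (`build_chain`) guarantees exact φ/ψ instead of exact rise and
provides extended (φ = ψ = 180°) conformations; unfolded frames use it,
which guarantees both helicity branches fail.

`simulate_two_state` runs a two-state Markov chain on {PR, NR} (default
stay probabilities 0.95, start state PR — simulations start from the
agonist-bound-like conformation), rotates the loop atoms by −40° about
the *fitted* loop axis for NR frames, substitutes the extended loop on
transient unfolding events, and adds i.i.d. Gaussian noise (default
σ = 0.3 Å, a typical per-atom fluctuation scale after alignment) to all
coordinates last.  The seed feeds two independent sub-streams (state
sequence incl. unfolding; noise), so the state path is reproducible
across noise levels.  Ground-truth labels and angles (0/−40/NaN) are
emitted per frame.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: no sterics or force field, no membrane, no
solvent beyond an optionally placed bridging water, rigid two-state
geometry rather than a continuous conformational ensemble, and uncorrelated
isotropic noise rather than collective fluctuations.  One consequence is
worth flagging: the PR→NR transition is a rigid rotation, so it leaves
internal dihedrals unchanged and is invisible to dihedral PCA on
synthetic data (the dPCA spectrum there is pure noise); the dPCA stack is
therefore validated through its own oracles (hand-built torsions, spectrum
versus power-iteration/trace, rotation invariance), not through cluster
recovery.

## Study conditions used in the analysis scripts and acceptance run

Two conditions × 3 replicates × 400 frames (80 ns at the default stride),
noise σ = 0.3 Å, unfolding probability 0.01/frame: the agonist-bound
analog with stay probabilities (PR 0.995, NR 0.80) and the
agonist-removed analog with (0.80, 0.995), both started in PR.  These
sizes keep the full study — generation, file round-trip, per-frame
metrics, statistics — to seconds while leaving every comparison
well-resolved: with 3 fully separated replicates per side the exact
two-sided Mann–Whitney p reaches its 3-vs-3 minimum of 0.1, PR fractions
differ by an order of magnitude, and the stationary-fraction check at
10⁴ frames sits within 3 standard errors by construction of the chain.

## Numerical conventions and degenerate inputs

Angles wrap to (−180, 180]; rotations follow the right-hand rule about
the axis direction.  Superposition refuses < 3 or collinear points;
helix fitting refuses < 5 residues; `axial_position` refuses zero-length
segments and reports the signed, unclamped projection; the axis-fitted
angle skips markers that land on the axis and fails only if both do.
Missing anchors raise a missing-atom error naming residue and atom;
selections matching multiple atoms raise an ambiguity error rather than
picking silently.  Empty replicate or frame series raise rather than
returning NaN.  In the pipeline, metrics whose anchors are absent are
skipped per-table with empty columns (a run over receptor-only data
simply has no Gα columns), while missing *files* abort before any
computation.

## Known limitations

Real crystal-structure checks (the 3 Å TM5 shift between the
agonist-bound and agonist-free FFAR1 forms, the four-bond initial
helix) are exercised here on constructed structures that impose the same
geometry; running them on the real PDB entries requires only the two
files and a landmark map (see `analysis/06_crystal_shift.py`).  The
plane-projection angle presumes the alignment leaves the loop axis near
x, as it does for TM1–TM4-aligned GPCR frames; for other systems use the
axis-fitted angle.  Water bridges are single-water only.  No
autocorrelation correction beyond replicate-level sampling; no
multiple-testing control.
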