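# Methods

This note records the geometric conventions, thresholds and design choices
behind every operation, what the synthetic generator does and does not
emulate, and the known limitations.

## Scope and model

The package quantifies the closed↔open conformational change of a
seven-transmembrane receptor as observed crystallographically: per-residue
backbone dihedrals and helical class along helix V, main-chain hydrogen-bond
geometry in its pliable M2 stretch, helix bend/advance metrics,
superposition-based RMSD and displacement between conformers, contact and
metal-coordination listings, and the bookkeeping of dual-conformation
(alternate-location) models. Crystallographic refinement, electron-density
interpretation and cavity rendering are out of scope: the package consumes
deposited coordinates and occupancies, it does not produce them.

Author residue numbering is used everywhere (the numbering publications
quote, e.g. Arg264); label-scheme numbering is not exposed. The default
region scheme partitions the mobile cassette as ICL2 255–263 and helix V as
NT 264–267 / M1 268–272 / M2 273–280 / CT 281–288, with the mobile region
250–288 and the dual-conformation range 250–279. Sources quote the NT
bound inconsistently (264–276 vs 264–267); the non-overlapping partition is
the default and every range is overridable.

## Hydrogen-bond criteria

X-ray depositions near 3 Å resolution carry no experimental hydrogens, so
amide hydrogens are always rebuilt: H at 1.00 Å from N, in the
C(i−1)–N–CA plane, opposite the bisector of the N→C(i−1) and N→CA unit
vectors. Proline and chain-initial residues get no hydrogen; residues with
missing backbone atoms or a broken peptide bond (C–N ≥ 2.0 Å) are skipped
and listed in a gap report.

A CO(i)···HN(j) candidate at helical offset j−i ∈ {3, 4} is a bond when

* the O···N distance, **rounded to one decimal**, is ≤ 3.5 Å, and
* the O···H−N angle **measured at the hydrogen** (180° = linear) is ≥ 130°,
* and the donor is not proline.

Rounding before comparison makes the criterion match how such distances are
reported (a 3.54 Å pair printed as "3.5" counts as a bond); a raw-value mode
is available (`GeometryConfig(round_distances=False)`). Bonds with rounded
distance in 3.2–3.5 Å are flagged *weak* — the regime that stabilises a
3₁₀ stretch without α-helical strength. The at-hydrogen angle convention is
the one under which reported rejected angles (~102–125°) and accepted ones
(~145–164°) are separable by a single 130° threshold.

Classification: a residue participating (as donor or acceptor) only in
offset-4 bonds is `alpha`, only in offset-3 bonds `three10`; with both, the
shorter O···N distance decides (ties → `alpha`); with neither,
`turn_or_none`. Every non-empty label is justified by at least one recorded
bond. Known limitation: under coordinate noise the two-sided rule can flip
single residues (an offset-3 contact in an α-helix sits near 3.1 Å with a
~107° angle; noise occasionally pushes the angle past 130° *and* makes it
the shortest supporting bond). At σ = 0.1 Å this affects well under 1% of
interior labels but means whole-segment correctness per realization is a
weaker guarantee (~93%) than per-label accuracy (~99.3%).

## Helix axes, bend and advance

Axes use the bisector construction: for Cα points on an ideal helix the
bisector (Cα(i−1)−Cα(i)) + (Cα(i+1)−Cα(i)) is exactly radial, so the axis
is the least-squares common normal of the bisectors (smallest principal
component of the normalized bisector set), oriented from the first to the
last residue of the requested range. This is exact on ideal helices of any
length — a line fit through running-average points was rejected because its
residual helical wobble tilts the fitted line by ~1° for segments covering
a non-integer number of turns, which is material when recovering bends of
10–30° to ±2°. Inter-axis angles are reported in [0, 180]; published
bend/tilt values of this kind (~18°, ~20°) are method-dependent and are
only reproduced to a few degrees by any estimator.

The *advance* is the straight-line |Cα(i) − Cα(i+span)| distance at one
decimal — deliberately not an axial projection, because the simple chord is
what the 10.5 Å standard α-helix benchmark refers to, and it needs no axis
estimate on irregular segments. Note the chord is not monotone in span
below one turn (the classic d(i,i+3) < d(i,i+2) inversion).

## Superposition and displacement

Superpositions are least-squares fits over proper rotations (Kabsch via
SVD with determinant correction); reflections are never used, so a mirror
pair is fitted with the best proper rotation and a large residual rather
than an improper one. Collinear point sets and fewer than three atoms are
rejected. Chain RMSDs pair Cα atoms by author number over residues modeled
in both chains — the residue-set ambiguity this leaves against published
whole-chain values is within ±0.05 Å.

Displacement measurements ("residue X moves by Y Å between forms") fit on
Cα of common residues *excluding* the mobile region (default 250–288) so
that the fixed body of the receptor defines the frame, then report
per-target |x_a − (R·x_b + t)|. Published displacement values may derive
from a slightly different frame; ±0.5–1.0 Å reflects that.

Dual-conformation models are split into complete single-conformer
structures (blank-altloc atoms shared, one label per output, labels cleared)
and each conformer is assigned the reference structure with the lowest
whole-chain Cα RMSD. The altloc-label→state convention of a deposition is
never assumed: assignment is always computed.

## Synthetic generator

The generator provides the ground truth the test-suite runs on. Backbones
are built by sequential internal-coordinate (NeRF) placement with standard
bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å and angles
CA–C–N 116.2°, C–N–CA 121.7°, and a **tetrahedral N–CA–C angle
(109.47°)** — the classic model-building choice for ideal helices. With it,
the textbook parameters emerge rather than being painted on: the
(−57°, −47°) α-helix has rise 1.50 Å/residue, 3.6 residues/turn and a
seven-residue advance of 10.5 Å; the (−49°, −26°) 3₁₀-helix has rise
1.95 Å/residue at 3.0 residues/turn. (With the frequently tabulated
τ = 111.2° those dihedrals give a 1.56 Å rise and a 10.9 Å advance —
incompatible with the standard benchmark values, which is why the
tetrahedral value is the default.) The carbonyl O lies in the peptide plane
trans to the next amide nitrogen. Interior (φ, ψ) of a noiseless helix
reproduce the spec values to 10⁻³°, which is the generator/analyzer
round-trip the dihedral code is tested against (and cross-checked against
gemmi's torsion convention).

Kinked helices rotate the fragment downstream of the hinge Cα — the hinge
residue's C/O plus all later residues — rigidly about an axis through the
hinge Cα perpendicular to the pre-kink axis. Because the pivot lies on the
rotation axis, every bond length is preserved, including Cα–C at the hinge;
the hinge ψ and the N–Cα–C angle re-derive to new values. Dual-conformer
files duplicate a residue range under altlocs A/B with conformer B rigidly
translated perpendicular to the helix axis by a stated displacement, and
stated fractional occupancies. Metal-site toys place a Zn ion with up to
four nitrogen ligands on exact tetrahedral directions.

Gaussian coordinate noise (σ in Å, seeded, per coordinate) emulates
coordinate uncertainty only. The generator does **not** emulate side chains
beyond the backbone, anisotropic/correlated positional error, missing
residues, sequence-dependent dihedral preferences, or crystal packing —
so passing synthetic tests demonstrates the correctness of the geometry
pipeline, not robustness to every pathology of real depositions; the
real-structure checks exist for that and run when the deposited entries are
available locally.

## Determinism, precision, degenerate inputs

All randomness flows through explicit integer seeds; identical specs give
bit-identical structures. Reported distances are rounded to 1 decimal and
angles to integer degrees where an operation is defined as "reported"
(named-atom distances, advance, hydrogen-bond tables); raw values are kept
internally and in programmatic records. Dihedrals are IUPAC-signed in
(−180°, 180°]. Chain breaks yield undefined dihedral entries, not
exceptions; missing displacement targets are listed and the remaining
targets still reported; an absent metal element warns and returns empty.
The analysis report captures per-stage failures and is emitted with gaps
flagged; it validates against the shipped minimal JSON schema.

Problem sizes used by the test suite and the acceptance script: helices of
12–50 residues, 1000 noise realizations for the classification accuracy
statistic, and a 5-atom brute-force rotation oracle (13×7×13 Euler grid +
simplex refinement) for the superposition check — all chosen to exercise
each property at the smallest scale where the ground truth is exact.
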