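# Methods

`qzipper` is a desk-scale reimplementation of a multiscale polyglutamine
(polyQ) aggregation workflow: geometric construction of polymorphic
steric-zipper fibril models, a multi-state native-contact (Gō-like) pair
potential learned from monomer, fibril, and dense-phase ensembles, a
coarse-grained Langevin engine that aggregates tens of chains under that
potential, and the standard fibrillation statistics (clustering
kinetics, t½, oligomer distributions, secondary structure, contact
maps).  This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic tests show.

## Fibril model construction

**Architecture.**  The minimal polyQ steric-zipper unit is one
16-glutamine chain folded into two six-residue antiparallel β-strands
joined by a four-residue turn.  Two tertiary folds are built:

* **β-turn (BT)** — the chain's strands are H-bonded side by side
  within one sheet (a hairpin); side chains interdigitate with a
  different chain across the sheet interface;
* **β-arc (BA)** — the chain's strands sit in adjacent sheets with
  their side chains interdigitating within the molecule; sheets form
  between strands of different chains.

Quaternary arrangements A1–A4 flip consecutive chains along the lateral
axis (none / lateral / axial / both).  The coordinate frame is recorded
on every lattice: lateral = H-bond direction (x), axial = sheet normal
and side-chain direction (y), stacking = strand backbone (z); the
lattice is treated as periodic in x and y (the two fibril growth
directions) and finite along the strand.

**Chain growth.**  Chains are grown atom by atom from ideal glutamine
internal coordinates (bond lengths/angles from the CCD ideal residue;
backbone angles from standard peptide values; an improper torsion fixes
L-chirality).  Strand residues carry the ssNMR-derived conformer
dihedrals exactly: ψ = 136°/150° and χ1 = −65°/+55° for the "a"/"b"
conformer classes on alternating strands, χ2 = 180° for both.  The
parity convention: strand 1 of each chain is class "a", strand 2 class
"b", so H-bonded neighbors within a sheet share a class in the BA fold
and alternate within the BT hairpin.

**Free geometric parameters.**  The ssNMR doublet and the diffraction
spacings (defaults 4.8 Å strand-to-strand, 8.3 Å sheet-to-sheet, both
configurable) leave several construction freedoms that we fix once by
deterministic steric-clearance scans, never per measurement:

* φ per conformer class (not observed by ssNMR): β-region values chosen
  per unit kind so the fixed χ1 rotamers do not collide with the
  backbone — χ1 = +55° collides with the preceding carbonyl for
  φ < −120°, which rules out a single shared φ default;
* the side-chain amide torsion χ3 per class (unobserved);
* a rigid "roll" of each strand about its own axis (the pleat
  azimuth, unobserved);
* the registration of strand 2 along the strand axis and the flip
  phase of the antiparallel transform;
* lattice registration: shears of successive chains and sheets along
  the strand axis, a lateral sub-shift of successive sheets, and
  bounded sub-offsets for flipped chains (mean spacings preserved).

**Turn closure.**  The turn's φ/ψ (plus the φ of the first strand-2
residue) are the only backbone freedoms; loop closure to the configured
strand-2 placement is an exactly determined 9-constraint / 9-unknown
problem solved by Levenberg–Marquardt from a bank of template starts
(solved turns are frozen as the defaults, so standard builds converge in
one pass).  Because closure solutions are isolated, the turn backbone
cannot trade closure against sterics; turn side-chain rotamers, which do
not enter the closure constraint, are placed by a greedy deterministic
clearance search, optionally against the lattice environment.

**Clash accounting.**  Interchain clash-freedom is enforced at 2.0 Å
(heavy-atom, brute force) on built lattices.  Intramolecularly the
rigid ideal-dihedral construction is genuinely overconstrained: the
b-strand's own O(i)–CG(i+1) pair sits near 2 Å by construction, and the
BT hairpin corner retains a sub-van-der-Waals contact between the first
turn residue and strand-2 side chains that only excluded-volume
relaxation can open.  The intra-unit guard is therefore per-kind (BT
1.2 Å, BA 1.7 Å) and the residual contacts are relaxed by minimization
before any dihedral validation.

**Relaxation and measurement.**  Excluded-volume minimization of a
heavy-atom lattice uses a restraint topology generated from the built
structure itself (bonds/angles/torsions restrained at built values;
k = 20 000 kJ/mol/nm², 300 kJ/mol/rad², 40 kJ/mol) plus a purely
repulsive nonbonded term (σ_rep = 3.0 Å), steepest descent to
max |F| < 1000 kJ/mol/nm.  Dihedral modes are computed as the argmax of
a von Mises kernel density (κ = 50) on a 0.25° grid; this keeps the
mode meaningful for multimodal or seam-straddling samples where a
circular mean would not be.  Spacings are measured from least-squares
strand axes and sheet planes; with the construction's sheared
registration these round-trip the configured values to well within
0.1 Å.

## Multi-state contact potential

Contacts are residue-pair events: two residues are in contact in a
frame when any heavy atom (or bead) of one is within 6 Å of the other.
Contact probabilities are fractions of frames (interchain: averaged
over ordered chain pairs, counted per contacting chain-pair instance).
Each record also stores:

* the mean distance between the residues' *representative* sites (the
  side-chain bead, or the CG atom of a heavy-atom glutamine) — the
  sites the bead projection will couple — so the derived pair minimum
  σ = d/2^(1/6) sits where the source geometry actually puts the beads;
* the contact *multiplicity*: the mean number of site pairs inside the
  cutoff per contact.  When the residue pair is projected onto a single
  bead pair, its well depth is ε × multiplicity.  This is the
  energy-preserving part of the resolution reduction: one bead pair
  stands in for 5–60 atomic contacts, and without the factor a
  residue-level projection of an atomic-resolution contact model
  underestimates cohesion roughly tenfold and produces no aggregation
  at any realistic concentration.

States merge with fibril > dense > monomer precedence (conflicts
logged): intramolecular contacts from the monomer ensemble (fibril-state
intramolecular contacts win where both claim a pair), polyQ-core
interchain contacts from the built β-arc A1 lattice, flanking-domain
interchain contacts from the dense phase.  Every interchain pair
coupling a flanking domain (N17 or P5) to the polyQ core is forced
repulsive — the excluded-volume contract that keeps flanking domains
from frustrating fibril growth.  Non-native pairs interact through
excluded volume only: U(r) = ε_ref[(σ_rep/r)¹² − 1] for r < σ_rep
(σ_rep = 0.35 nm for beads), zero beyond.  Native pairs use 12-6
Lennard-Jones truncated and shifted at the 1.45 nm cutoff; the shift
moves the well minimum above −ε by < 1 %.

The reference interaction strength is ε = 0.4 kJ/mol (Q16) and
0.325 kJ/mol (H16), assigned flat to every native pair; a
probability-weighted mode (ε·p_ij) is available as a switch.
Calibration against a reference ensemble scores each grid ε by the
1-Wasserstein distance between single-chain radius-of-gyration
distributions plus a 0.5-weighted mean-L1 contact-map term, and returns
the argmin; on self-generated references it recovers the generating ε
within one 0.05 kJ/mol grid step.

## Coarse-grained engine

Two beads per residue (backbone at CA, 57 amu; side chain at CG,
72 amu).  Transferable bonded terms, fit once to the builder's ideal
strand/helix backbone traces: bonds r0 = 3.81 Å (CA–CA) and 2.55 Å
(CA–SC) with k = 8000 kJ/mol/nm²; soft angles (θ0 = 127°/110°,
k = 20 kJ/mol/rad²) and a weak extended-biased backbone pseudo-dihedral
(k = 0.5 kJ/mol), so contacts rather than bonded terms select secondary
structure.  Dynamics: BAOAB ("middle") Langevin splitting, default
10 fs timestep, friction 1 ps⁻¹, 300 K; forces are exact analytic
gradients (verified against central differences to < 10⁻⁵ relative).
Nonbonded bookkeeping uses Verlet lists with a 0.3 nm skin rebuilt on
half-skin displacement: a brute-force O(N²) scan for the short-ranged
repulsion and an activity filter over the explicit native-pair table
(the bead counts here, ≤ ~1600, make cell binning unnecessary).
Minimization is adaptive steepest descent with a non-increasing energy
guarantee.  Identical seed and state reproduce trajectories bitwise.

System setup places chains drawn from a conformer pool at random
positions/orientations with rejection below 0.4 nm interchain,
Maxwell–Boltzmann velocities, in a cubic box sized from
(n/(N_A·c))^(1/3).  A semi-infinite mode restricts periodicity to X, Y
with a reflective wall in Z.

## Aggregation statistics

Chains cluster by single-linkage connectivity with a 10 Å Cα–Cα cutoff
(minimum image); components come from the sparse graph machinery and
are oracle-tested against brute force.  The kinetics trace records the
monomer fraction (size-1 clusters) and largest-cluster fraction per
frame; t½ is the first, linearly interpolated, crossing of monomer
fraction 0.5.  Oligomer distributions pool cluster sizes over frames in
[t½, t½ + horizon] (default horizon 200 model-ns) or [0, t½) and report
the percentage of chains per oligomer order.

Secondary structure: heavy-atom structures are scored with the
Kabsch–Sander H-bond energy criterion (amide H rebuilt from the
preceding carbonyl; bond below −0.5 kcal/mol) with the standard
parallel/antiparallel bridge patterns and two-consecutive-turn helices;
bead structures fall back to Cα pseudo-angle/dihedral windows centred
on the builder's ideal strand and helix traces (strand: angle
100–160°, |dihedral| ≥ 135°; helix: angle 75–105°, dihedral 25–75°).
Chains shorter than four residues are coil.  The end-to-end classifier
labels a domain extended when its first-to-last Cα distance strictly
exceeds 3.5 nm — the midpoint gap between the built zipper units
(< 2 nm) and the ideal extended 16-mer (≈ 5.1 nm).

## Synthetic data

The generators supply every pipeline input with known ground truth:
self-avoiding biased random-walk coil ensembles (bond 3.81 Å, excluded
volume 3.65 Å, tunable persistence; radius of gyration is computed over
backbone beads); labeled monomer/oligomer mixtures built with 6 Å
intra-cluster stacking and ≥ 15 Å inter-cluster margins so clustering
recovery is exact by construction; exponential monomer-depletion traces
with binomial sampling noise (note that the first-crossing t½ estimator
is systematically early at small chain counts — at n = 10 the measured
mean is 30.7 ± 7.5 against ln2/k = 69.3); and crowded dense-phase boxes
whose head-to-head/tail-to-tail chain pairing produces the
flanking-block contact enrichment of a dense phase without simulating
one.  All generators are deterministic under a fixed seed and record
their configuration in output metadata.

## Scale, study conditions, and limitations

The published experiment runs 500–1000 united-atom chains for
microseconds; this package deliberately runs 16–64 two-bead chains for
nanoseconds of model time, so published full-scale kinetic numbers
(plateau β-fractions, oligomer percentages, helicity profiles) are out
of reach by design and replaced by property-level expectations.  The
aggregation demonstration uses 24 Q16 chains at 40 mM — an elevated
effective concentration that compresses nucleation and coalescence into
a tractable run — with friction 0.05 ps⁻¹ during production purely as
kinetic acceleration (Langevin friction does not alter equilibria).
Under these conditions all chains typically join a single cluster
within ~1 ns of model time and the bead-level β-fraction rises from its
coil baseline (~0.2) as chains zip; passing this says the engine and
potential drive cooperative, contact-specific assembly, not that the
model reproduces experimental fibrillation kinetics.

Other known limitations: the idealized rigid construction leaves
sub-2 Å intramolecular contacts (above), and for the flipped
arrangements (A2–A4, and BT generally) the rigid interchain packing
sits below 2.0 Å however the free registration parameters are chosen —
construction therefore ends with the restrained excluded-volume
relaxation described above, exactly as the field's own system
preparation does, and only the β-arc A1 lattice (the arrangement the
fibril contacts are learned from) ships fully rigid.  The relaxed
lattices keep their mean spacings within 0.1 Å and their strand
dihedrals within 5° of the conformer values.  Bead-mode secondary
structure is a pseudo-dihedral heuristic, not DSSP; the rigid lattices
have no true backbone H-bond register (the hydrogen-bond assigner
correctly reports them as coil, which is why fibril fixtures are scored
at bead level); the dense-phase generator reproduces the block
statistics of flanking-domain contacts, not their physics; and model
time is not calibrated to experimental time in any way.
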