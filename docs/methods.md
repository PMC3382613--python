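# Methods

## Scope and model

`vasite` predicts volatile-anesthetic binding sites on an ensemble of
protein conformations and estimates the pharmacology of the resulting
binding energies. The pipeline treats the receptor as rigid within each
dominant conformation; protein flexibility enters only through the
ensemble. Solvent is absent everywhere: pockets are geometric/chemical
features (buried, hydrophobic), and docking energies are gas-phase
pairwise sums. These are the standard assumptions of surface-geometry
site prediction and grid docking, and they bound what the numbers mean —
relative comparisons within a run are meaningful, absolute binding free
energies are not.

## Ensemble clustering

Frames are compared by all-atom RMSD after an optimal least-squares rigid
superposition (Kabsch, via `scipy.spatial.transform.Rotation`);
superposition is on by default and exposed as a flag. Clustering is
single linkage with a 1 Å cutoff, implemented through
`scipy.cluster.hierarchy`; flat clusters at the cutoff equal the connected
components of the graph with an edge wherever RMSD ≤ cutoff, which is the
property the tests pin against a brute-force union-find oracle.

Cluster occupancy is reported as a simulation fraction
f_c = 100·n_c/N rounded to two decimals, with a dense rank (ties share a
rank, the next distinct value takes the next integer). Σf_c can deviate
from 100% by at most 0.01 per cluster due to rounding.

Representatives default to the coordinate mean after superposing all
members onto the lowest-index member. Averaged structures can carry
distorted stereochemistry; that is accepted and recorded here because the
representative only serves distance-based pocket detection. A `medoid`
mode (member minimizing summed RMSD) is provided for workflows that need
a physical snapshot.

## Pocket detection

A conformation is coated with probe spheres of radius 1.8 Å. Layer-0
probes are points of a 0.5 Å grid that are clash-free (no heavy atom
closer than atom radius + probe radius − 0.5 Å) and contact at least
three atoms (within atom radius + probe radius + 0.5 Å); later layers
(up to 3) accrete clash-free grid points adjacent to surviving probes
with at least two contacts. A probe survives only if its burial count —
heavy atoms within 8 Å — reaches 55. Grid seeding is an equivalent,
deterministic replacement for triplet-tangency placement; the contract is
the recall property (every engineered cavity found, nothing on convex
surface), verified against an exhaustive grid-scan oracle, not bit-level
equivalence with any particular implementation. The probe, burial radius,
threshold and layer count are the classic probe-sphere cavity-detection
values; all are config keys.

Surviving probes merge into sites by connected components at 3 Å; the
site center is the burial-weighted centroid and the score the summed
burial counts. The anesthetic-specific step is the hydrophobicity filter:
a site is kept iff hydrophobic heavy atoms are ≥ 50% (inclusive) of the
heavy atoms within 5 Å of its center. Hydrophobicity is a residue-level
lookup, Kyte–Doolittle index > 0 ⇒ {ILE, VAL, LEU, PHE, CYS, MET, ALA},
shipped as an editable table (`data/hydrophobicity.tsv`); unknown residue
codes count as not hydrophobic and warn. All distance-based operations
use heavy atoms only — hydrogens, when present, are ignored; whether the
original protocols included hydrogens is not recorded anywhere we could
verify, so heavy-atom-only is this package's choice. Site output is
sorted by descending score then lexicographic center, and floating
comparisons at inclusive boundaries use a 1e-9 tolerance, so results are
order-independent and deterministic.

## Consensus and persistence

Per-conformation sites are grouped across the ensemble by DBSCAN with
minimum group size 1 and neighbor distance 5 Å between site centers.
With minimum size 1 no noise points exist and the grouping equals
connected components of the ≤5 Å graph; the implementation is the
components computation (scipy sparse graphs), with scikit-learn's DBSCAN
kept as the independent oracle in the test suite. Group centers are the
arithmetic mean of member site centers. Distances are between site
centers — grouping in a shared reference frame presumes the ensemble is
superposed, which holds for our generators (bounded noise around a base
structure) and for trajectory representatives fitted during RMSD
computation.

Persistence is the sum of simulation fractions over the *distinct*
dominant conformations containing at least one member site; duplicates
within one conformation count once. It is reported to two decimals and is
monotone in membership, reaching Σf_c = 100% (± rounding) for a site
found everywhere.

Residue annotation takes every residue with ≥ 1 heavy atom within 5 Å of
the group center, measured on the representative of the member
conformation with the highest simulation fraction (the tables this
mirrors do not state their reference structure; the highest-occupancy
conformation is the least arbitrary single choice). Residue numbering is
never re-indexed. Interface classification maps monomer labels through a
user-supplied lattice table (α/β type, dimer index, protofilament index):
one monomer → body class; α+β of one dimer → intradimer; two dimers on
one protofilament → longitudinal; two protofilaments → lateral, suffixed
by the monomer types involved. Reference drug/nucleotide/zinc residue
sets ship as data (`data/reference_sites.json`) and overlap is computed
on (monomer type, residue number).

## Docking

The scorer is a deliberate simplification: a 12-6 Lennard-Jones term with
Lorentz–Berthelot combining (r_min = r_i + r_j, ε_ij = √(ε_i ε_j)) plus a
Coulomb term 332.06·q_iq_j/(ε(r)·r) with distance-dependent dielectric
ε(r) = 4r, pair cutoff 12 Å. Desolvation, directional hydrogen bonds and
torsional entropy are *not* modeled, so energies are not comparable to
published grid-docking force-field values; the meaningful outputs are
structural (where the best pose sits, which atoms dominate the
decomposition, how pose families rank). Pairs closer than 0.1 Å are
evaluated at 0.1 Å and flagged rather than returning infinities.

Search precomputes receptor fields on a grid (one LJ map per ligand atom
class, one electrostatic map; trilinear interpolation; values clamped at
10⁴ kcal/mol so optimizers see steep but finite walls), then runs seeded
random restarts over translation, orientation (uniform random rotations)
and the rotatable torsion, each refined by Powell minimization on the
maps (defaults: 12 restarts × 150 evaluations; both config keys — the
budget is this package's own, since stochastic-search internals do not
transfer between implementations). Final pose energies are always
recomputed by direct summation, so grid resolution never touches reported
numbers; the grid's fidelity contract (within 0.1 kcal/mol of the direct
sum) is tested in the smooth attractive regime on a planar fixture, where
interpolation error is meaningful — on the clamped repulsive walls only
the ordering matters. Focused mode uses a 10 Å cubic box at 0.375 Å
spacing; blind mode boxes the molecule's bounding box plus a 4–5 Å
margin (the tail drivers default to 0.75 Å spacing to keep large blind
boxes tractable; spacing is a config key).

Halothane is built from an internal-coordinate (Z-matrix) template by
NeRF construction with IUPAC right-handed dihedrals. The template's bond
lengths, angles and partial charges are standard gas-phase values
transcribed by the implementer (the authoritative figure exists only as
an image); every geometric test therefore asserts round-trip consistency
(rebuilt internal coordinates match the template to 1e-6 Å / 1e-4°),
never specific transcribed numbers. The single rotatable torsion is the
CF₃–CHClBr bond, driven through the dihedral of the H atom with Cl and Br
defined relative to it so the group turns rigidly.

Poses cluster by greedy leader assignment in energy order at 2 Å ligand
RMSD without superposition (poses share the receptor frame). The
reported energy is the best energy of the largest cluster — multiple
binding modes are resolved by population, not by global minimum — with
size ties going to the lower-energy cluster.

## Pharmacology

K_d = exp(ΔG/RT)·1 M with R = 1.987×10⁻³ kcal/(mol·K). The default
temperature is 310 K (physiological): the source analysis states no
temperature, and 310 K is the value under which its printed millimolar
range follows from its most-persistent-site energies (−2.54 → 16 mM,
−3.12 → 6.3 mM), whereas 298 K does not reproduce it. Occupancy is the
single-site equilibrium θ = [L]/([L]+K_d); no cooperativity, no multiple
affinity classes, no kinetics. The MAC mapping (1–2 MAC ≈ 250–500 µM
halothane) is a quoted constant, not a computed one. A
significant-figure helper (`round_sig`) provides the 1–2 significant
figure reporting used for these quantities, since the quantities
themselves are order-of-magnitude estimates.

## Synthetic data: what it emulates, and what it does not

The generators reproduce exactly the properties the pipeline consumes:

* **Toy receptors** are filled balls of carbon-like pseudo-atoms
  (concentric shells, 2 Å apart, areal density 0.12 atoms/Å², atom radius
  1.5 Å) with spherical chambers carved out and walled by a denser lining
  (0.2 atoms/Å²) whose residue names realize a prescribed hydrophobic
  fraction. The solid interior matters: a hollow shell's inside is itself
  one giant buried cavity and floods the burial filter. Default chamber
  radius is 3.5 Å (detectable by 1.8 Å probes); halothane-sized docking
  chambers use radius 5 Å. Densities were chosen once so that burial
  counts separate cleanly around the 55-atom threshold — cavity interiors
  reach roughly three times the threshold while convex surface points
  stay well under it — and are not tuned per test.
* **Two-regime ensembles** add bounded noise (uniform in a 0.1 Å ball per
  atom) around two base geometries: the open receptor, and a closed form
  in which one cavity's lining is scattered through its chamber volume
  (blocking all probe positions) and the whole body carries a
  volume-preserving anisotropic strain (z ×1.25, x,y ÷√1.25). The strain
  separates the regimes by >1 Å RMSD — robustly across the clustering
  cutoff — while keeping the body convex and void-free; localized
  deformations tried first (surface bulges, shell lifts) opened spurious
  buried gaps and were rejected.
* **Tail conformers** are self-avoiding chains with two pseudo-atoms per
  residue (CA–CA 3.8 Å, side-chain offset 2.4 Å, minimum nonbonded
  distance 2.0 Å). A per-conformer directional persistence swept from
  0.95 to 0 spans extended to compact shapes (radius-of-gyration ratio
  ≥ 1.5 by construction, typically ≈ 3). Side-chain directions pick the
  least crowded of eight candidates; a conformer failing self-avoidance
  after bounded retries raises with its seed.

What the generators do **not** emulate: real secondary structure,
side-chain rotamers, solvent, realistic charge distributions, or the
actual tubulin fold. Passing tests therefore demonstrate that the
*algorithms* behave as specified on inputs with known ground truth — not
that the specific published site list or energies are recovered, which
would require the original (undeposited) trajectory and force field.

## Problem sizes and determinism

The test suite and acceptance script run scaled-down problem sizes chosen
as this package's own defaults: 14-frame two-regime ensembles for
end-to-end checks (the fixture generator writes the full 251 frames),
8–12 docking restarts, 5–8 tail conformers per trend estimate, and
10 generator seeds for the cavity-recall property. Every stochastic stage
takes an explicit seed; identical config + seeds produce byte-identical
report files (fixed float formats, sorted JSON keys, a config digest that
ignores the output directory).

## Known limitations

* The scorer's absolute energies are surrogate-scale; only structure and
  ordering are interpretable.
* Pocket detection assumes a roughly superposed ensemble and carries no
  concept of channel accessibility — a fully enclosed cavity is found
  (grid seeding reaches it), which matches the buried-cavity biology here
  but differs from surface-walking implementations.
* Interface classification requires a user-supplied chain→lattice map;
  synthetic receptors are single-chain, so their sites report no
  interface class.
* DBSCAN with minimum group size > 1 is accepted but warns: it can drop
  sparse sites as noise and deviates from the grouping protocol this
  package mirrors.
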