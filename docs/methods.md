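# Methods

## Model

A ligand–receptor complex is reduced to a labeled undirected graph of its
binding interface. Interfacial atoms are defined *by tessellation, not by a
raw distance scan*: the Delaunay tessellation of all heavy atoms gives a
sparse, well-shaped contact structure, and only tessellation edges that
cross between the receptor and ligand sides (or either side and water, when
waters are kept) within the distance cutoff mark their endpoints as
interfacial. Covalent neighbors of interfacial atoms are added as padding
nodes: they sharpen the chemical description of the interface and supply the
atoms that complete extracted fragments. Node labels are SYBYL atom types
(the closed 41-type vocabulary, element + hybridization/environment);
hydrogens have no type in that vocabulary and are excluded everywhere. Edge
labels are the covalent bond types `1/2/3/am/ar` or `nc` for non-covalent
contacts; every edge stores its length in Å.

Pocket similarity is receptor-side subgraph isomorphism with geometric
verification: connected induced subgraphs of the target receptor side,
within a user size range, are embedded into database receptor sides under
exact node- and edge-label equality, filtered by per-edge length agreement,
and accepted when the matched nodes superimpose (proper rotation only) with
RMSD below a cutoff. Accepted matches drive fragment extraction: the
database ligand atoms in `nc` contact with the matched pocket, plus their
covalent ligand neighbors, are mapped into the target frame by the match's
rigid transform, and atoms violating a safety distance to the target
receptor are deleted as collisions.

## Almost-Delaunay relaxation

Experimental coordinates are imprecise; a contact that would appear in the
tessellation of slightly perturbed coordinates should not be lost to a
rounding artifact. An edge is *Almost-Delaunay at level ε* if some
perturbation of the points, each displaced at most ε, makes it a Delaunay
edge. We estimate membership by resampling rather than by exact minimal
perturbation analysis: seeded unit displacement fields (uniform in the unit
ball, one per replicate; 20 replicates by default) are applied at a fixed
absolute ladder of scales (0.005–1.0 Å), and an edge is AD(ε) if it appears
in any replicate at a scale ≤ ε. Its recorded `min_perturbation` is the
smallest such scale (0 for the exact Delaunay core). Because the
displacement fields do not depend on ε, the construction guarantees the two
contract properties exactly: AD(0) is the exact Delaunay edge set, and
AD(ε) is monotone non-decreasing in ε. The estimate is a lower bound on the
true AD set (resampling can miss a feasible perturbation); with the default
ε = 0.01 Å it is a mild relaxation that only fires near-degenerate
configurations.

Degenerate geometry (coplanar/cospherical inputs, 4-point minimal inputs)
is handled by a deterministic 1e-6 Å jitter seeded from the point indices;
complexes with fewer than 5 heavy atoms fall back to the all-pairs distance
graph within the cutoff, where tessellation is undefined.

Intra-side tessellation edges between interfacial atoms are kept (as `nc`
edges) alongside the cross-side contacts: receptor-side matching needs
receptor–receptor edges to exist, or no connected receptor subgraph larger
than a covalent fragment could form.

## Matching machinery

**Canonical codes.** Connected induced subgraphs are canonicalized by a
branch-and-bound search for the lexicographically minimal connected
adjacency code: vertices are appended one at a time (always adjacent to the
chosen prefix), each contributing a row (node label, sorted (earlier
position, edge label) pairs), and only orderings achieving the minimal next
row survive. The code fully determines the labeled graph, so equal codes ⇔
isomorphic labeled subgraphs. Edge lengths are deliberately excluded from
the code: geometry is continuous and is checked per-embedding instead.

**Growth.** Connected induced subgraphs are enumerated exactly once each by
ESU-style extension (extension sets restricted to higher-ordered, exclusive
neighbors), and deduplicated by canonical code. A pattern keeps *all* its
occurrences (node tuples in canonical vertex order), so isomorphic but
spatially distinct target subgraphs each remain matchable.

**Embedding.** Backtracking in canonical vertex order (every next vertex
attaches to an already-placed neighbor), with exact label equality, induced
adjacency (non-edges must map to non-edges), and candidate lists indexed by
label. A per-pattern embedding cap (default 10,000) guards the NP-complete
worst case; truncation is logged.

**Geometry.** Corresponding edge lengths must agree within
`distance_tolerance` (default 0.2 Å = 2 × the RMSD cutoff — a cheap
necessary condition applied before superposition). Superposition uses the
closed-form Kabsch solution (SVD with determinant correction), which is
restricted to proper rotations: mirror-image pockets are chemically
distinct and must not match. Matches with identical target and database
node *sets* related by an automorphism are collapsed to the lowest-RMSD
embedding; output order is deterministic (size desc, RMSD, node ids), so
identical inputs yield byte-identical reports.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `cutoff` | 5.8 | Å | max tessellation-edge length counted as a contact; lower it to focus on short-range (H-bond/ionic) interactions, raise it for hydrophobic pockets |
| `epsilon` | 0.01 | Å | AD perturbation level; absorbs coordinate imprecision |
| `min_size`, `max_size` | 8, 8 | atoms | accepted match size range; larger = more specific, smaller = more promiscuous |
| `rmsd_cutoff` | 0.1 | Å | superposition acceptance threshold |
| `distance_tolerance` | 0.2 | Å | per-edge length prefilter (2 × rmsd_cutoff) |
| `safety_distance` | 1.95 | Å | collision shell around target receptor atoms |
| `include_waters` | false | — | keep waters as potential bridging nodes |
| `embedding_cap` | 10,000 | — | embeddings per (pattern, database graph) |
| `ad_replicates` | 20 | — | resampling replicates per AD ladder scale |
| `seed` | 0 | — | seeds the AD resampling (the rest is deterministic) |

## File handling

MOL2 is authoritative for ligands (it carries SYBYL types and bonds); types
outside the closed vocabulary are a parse error naming the line, while
hydrogens, dummies and lone pairs are silently dropped with their bonds.
PDB receptors (read via gemmi, highest-occupancy altloc kept) are typed by
a fixed (residue, atom name) rule table for the 20 standard amino acids —
our construction, since PDB files carry no types: backbone N/CA/C/O →
N.am/C.3/C.2/O.2, OXT → O.co2, aromatic rings typed C.ar/N.ar (including
HIS and TRP ring nitrogens), LYS NZ → N.4, ARG CZ → C.cat, carboxylates →
O.co2. Other residues fall back to element-level types; elements outside
the vocabulary are dropped with a warning. Covalent bonds in PDB input are
perceived by the distance rule d < r_cov(a) + r_cov(b) + 0.45 Å (Cordero
radii); bond orders default to single with rule-based amide (N.am–C.2),
aromatic (same-residue ar–ar) and carbonyl (C.2–O.2/O.co2) refinement.
Metal contacts are coordination, not covalence, and are not perceived as
bonds; metals enter the graph as isolated typed nodes. Waters are
recognized by residue name (HOH/WAT/H2O/…).

Fragment output writes MOL2 (or SDF) with 1e-6 Å coordinate precision plus
a TSV manifest (fragment id, source complex, match index, RMSD, atom count,
component count, duplicate flag). Duplicated fragments from automorphic
matches are flagged by a rounded-coordinate hash, not dropped. Fragments
may be disconnected after collision pruning; they are emitted as one entry
with the component count recorded.

## Synthetic fixtures

The fixture generator emulates the *contact statistics* of a complex, not
protein geometry: a receptor of 24 heavy atoms (default) on a 1.5 Å-spaced
lattice walk with 0.25 Å positional jitter and chain covalent bonds
(single, 15% amide); a 4-atom ligand chain placed 3 Å beneath the
receptor's bottom face so that a chosen fraction of its atoms (default
0.75) lies within the 5.8 Å cutoff, the rest pushed beyond it; labels drawn
from a reduced 10-type alphabet to keep match multiplicity interpretable;
optional interface waters. Planted-pocket databases embed one complex's
interfacial receptor shell (plus covalent padding) and its ligand into a
decoy under a seeded random rigid transform, at ≥ 15 Å clearance from the
host's own atoms, with optional coordinate noise and label mutations; the
planting transform and atom mapping are returned as ground truth.
Coordinate noise is parameterized by the RMS magnitude of the per-atom 3D
displacement (each coordinate N(0, noise/√3)): 0.05 Å noise leaves the
planted correspondence well inside the 0.1 Å RMSD cutoff, 0.5 Å pushes it
far outside, so specificity tests have an unambiguous expected outcome.

What passing fixture tests does *not* show: behavior on real protein
packing densities (fixture interfaces are kept small — roughly 10–20
receptor-side nodes — so exhaustive oracles and full searches run in
seconds; real interfaces at cutoff 5.8 Å are larger and pattern counts grow
combinatorially with interface size), realistic B-factor noise structure,
alternate conformations, or chemically meaningful label distributions.

## Verification design

Every nontrivial computation is checked against an independent oracle at
small scale: tessellation against the brute-force empty-circumsphere
definition over all 4-subsets; canonical codes against pairwise VF2
isomorphism classes; the matcher against exhaustive enumeration of all
connected induced subgraphs × all label-preserving bijections; Kabsch
against a rotation-grid/Nelder-Mead optimum and scipy's `align_vectors`;
fragment frames against the analytic inverse transform; planted-pocket
recovery against the known planting transform. Problem sizes in tests and
in `scripts/acceptance.py` (graphs ≤ 12 nodes for exhaustive comparisons,
16–24-atom receptors, databases of ~11 entries, 30-point tessellations)
are chosen so each oracle is exact and the whole suite completes in
minutes.

## Known limitations

- The AD resampling estimate can under-count AD edges relative to exact
  minimal-perturbation analysis; it never under-counts the ε = 0 core.
- Exact SYBYL-type equality is strict: a pocket differing by one
  protonation-dependent type will not match (an element-level coarsening is
  available via `element_labels`).
- Subgraph matching remains exponential in the worst case; the embedding
  cap truncates pathological cases with a logged warning rather than
  running unbounded.
- PDB typing covers the 20 standard amino acids and common metals; modified
  residues degrade to element-level types.
- No protonation, charge assignment, structure repair, docking, scoring or
  pose optimization; fragments are reported as copied, not re-optimized.
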