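# fragvlib

Pocket-similarity search over databases of ligand–receptor complexes, and
extraction of the ligand fragments bound to matched pockets into the frame of
a target receptor — a **fragment-based virtual library** for structure-based
drug design (fragment-based lead discovery, bioisostere hunting, idea
generation).

## Who this is for

Computational chemists and structural bioinformaticians who have a target
receptor (with a bound ligand, or a hand-built pseudo-ligand marking the
pocket) and a directory of native complexes (e.g., a PDBbind-style layout),
and who want every ligand fragment that some database complex binds in a
pocket geometrically and chemically similar to the target's.

## Method

1. **Interfacial graph.** All heavy atoms of a complex are tessellated
   (Delaunay, relaxed to *Almost-Delaunay*: an edge also counts if it becomes
   Delaunay under a coordinate perturbation ≤ ε, absorbing experimental
   imprecision). Tessellation edges that cross between receptor and ligand
   within a distance cutoff define the *interfacial atoms*. These atoms, plus
   their covalently bonded neighbors, become nodes labeled with SYBYL atom
   types (C.3, N.am, O.co2, …, Zn — a closed 41-type vocabulary); edges are
   labeled with the covalent bond type (1/2/3/am/ar) or `nc` (non-covalent
   contact) and carry the interatomic distance. Waters are omitted by
   default; if kept they may bridge the two sides.
2. **Receptor-side subgraph match.** Every connected induced subgraph of the
   target's receptor side within a user-set size range is enumerated once per
   isomorphism class via canonical-code growth (stepwise extension restricted
   to connected subgraphs; a canonical string deduplicates symmetric
   re-discoveries). Each pattern is embedded into a database complex's
   receptor side under exact node- and edge-label equality, prefiltered by
   per-edge length agreement, and accepted only if the matched nodes
   superimpose by a proper rotation (Kabsch) with RMSD ≤ cutoff.
3. **Fragment extraction.** For each accepted match, the database ligand
   atoms in direct `nc` contact with the matched pocket (plus covalent ligand
   neighbors) are copied into the target frame by the match's rigid
   transform; atoms closer than a safety distance to any target receptor atom
   are deleted as collisions. Each fragment records its source complex and
   match RMSD.

Defaults: cutoff 5.8 Å, ε 0.01 Å, match size 8 atoms, RMSD cutoff 0.1 Å,
safety distance 1.95 Å, waters removed.

## Worked example

No downloads needed — the `fragvlib.fixtures` module generates synthetic
complexes and planted-pocket databases with known ground truth:

```python
import fragvlib as fv

# target: a synthetic 24-atom receptor with a 4-atom ligand, 3 in contact
target = fv.make_complex(fv.FixtureSpec(seed=42))

# database: 5 decoys, one of which hosts the target's pocket planted under
# a random rigid transform with 0.05 A coordinate noise
decoys = [fv.make_complex(fv.FixtureSpec(seed=4200 + i)) for i in range(5)]
database, truth = fv.plant_pocket(target, decoys, transform_seed=7,
                                  coord_noise=0.05, out_dir="db")

library, matches = fv.run_search(target, "db", fv.SearchConfig(),
                                 out_dir="out")
for cid in sorted(matches):
    ms = matches[cid]
    best = min((m.rmsd for m in ms), default=None)
    print(f"{cid}: {len(ms)} matches" +
          (f", best RMSD {best:.4f} A" if ms else ""))
print(f"library: {len(library.fragments)} fragments")
```

prints

```
syn4200_planted: 119 matches, best RMSD 0.0314 A
syn4201: 0 matches
syn4202: 0 matches
syn4203: 0 matches
syn4204: 0 matches
library: 119 fragments
```

The planted entry — and only the planted entry — is matched, at an RMSD set
by the 0.05 Å planting noise, well inside the 0.1 Å acceptance cutoff; every
size-8 receptor subgraph that overlaps the planted pocket yields one match
and one extracted fragment. `out/` then contains `fragments.mol2` (all
fragments, in the target frame, one entry per match), `matches.tsv`,
`manifest.tsv` and `run_metadata.json` with the full parameter record.

The same search from the shell:

```bash
fragvlib search --receptor target_protein.mol2 --ligand target_ligand.mol2 \
    --database db --out out
fragvlib graph --receptor target_protein.mol2 --ligand target_ligand.mol2 --out g
fragvlib selfcheck --seed 1
```

A pseudo-ligand (`--pseudo-ligand pocket_probe.mol2`) can replace a bound
ligand to delineate the pocket, or restrict the search to part of it.

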