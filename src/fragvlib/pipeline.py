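"""Search orchestration: target vs. database, with reproducible outputs.

The defaults reproduce the program's reference parameterization: AD
distance cutoff 5.8 Å with epsilon 0.01 Å, an accepted sub-graph match
size of 8 atoms, a maximum RMSD cutoff of 0.1 Å, a collision safety
distance of 1.95 Å, and water molecules removed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from . import __version__
from .fragment_extract import (FragmentLibrary, assemble_library,
                               extract_fragment)
from .interface_graph import build_interface_graph
from .pocket_match import MatchParams, find_matches, grow_patterns, write_match_tsv
from .structure_io import MolecularComplex, read_complex, write_fragments

logger = logging.getLogger("fragvlib.pipeline")


@dataclass
class SearchConfig:
    """Full parameter record of one search run."""

    cutoff: float = 5.8
    epsilon: float = 0.01
    min_size: int = 8
    max_size: int = 8
    rmsd_cutoff: float = 0.1
    safety_distance: float = 1.95
    include_waters: bool = False
    distance_tolerance: float = 0.2
    seed: int = 0
    embedding_cap: int = 10_000
    ad_replicates: int = 20
    element_labels: bool = False

    def match_params(self) -> MatchParams:
        return MatchParams(min_size=self.min_size, max_size=self.max_size,
                           rmsd_cutoff=self.rmsd_cutoff,
                           distance_tolerance=self.distance_tolerance,
                           embedding_cap=self.embedding_cap,
                           element_labels=self.element_labels)

    # flat key:value config text, mirroring the CLI flags
    def to_text(self) -> str:
        return "".join(f"{f.name}: {getattr(self, f.name)}\n"
                       for f in fields(self))

    @classmethod
    def from_text(cls, text: str) -> "SearchConfig":
        casts = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        values = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"config line {lineno}: expected 'key: value'")
            key, raw = (s.strip() for s in line.split(":", 1))
            if key not in casts:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            else:
                values[key] = type(current)(raw)
        return cls(**values)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "SearchConfig":
        return cls.from_text(Path(path).read_text())


def discover_database(database_dir: str | Path) -> list[tuple[str, Path, Path]]:
    """Find (id, receptor file, ligand file) entries in a database directory.

    Two layouts are auto-detected: PDBbind-style subdirectories
    (``<id>/<id>_protein.mol2`` + ``<id>/<id>_ligand.mol2``, pdb accepted
    for the protein) and flat ``<id>_protein.* / <id>_ligand.*`` pairs.
    """
    database_dir = Path(database_dir)
    entries: list[tuple[str, Path, Path]] = []

    def _find(stem_dir: Path, cid: str) -> tuple[Path, Path] | None:
        receptor = ligand = None
        for ext in (".mol2", ".pdb", ".ent"):
            cand = stem_dir / f"{cid}_protein{ext}"
            if receptor is None and cand.exists():
                receptor = cand
        lig = stem_dir / f"{cid}_ligand.mol2"
        if lig.exists():
            ligand = lig
        if receptor and ligand:
            return receptor, ligand
        return None

    for sub in sorted(p for p in database_dir.iterdir() if p.is_dir()):
        found = _find(sub, sub.name)
        if found:
            entries.append((sub.name, *found))
    if not entries:  # flat layout
        ids = sorted({p.name.rsplit("_protein", 1)[0]
                      for p in database_dir.glob("*_protein.*")})
        for cid in ids:
            found = _find(database_dir, cid)
            if found:
                entries.append((cid, *found))
    return entries


def run_search(target: MolecularComplex | tuple,
               database,
               config: SearchConfig | None = None,
               out_dir: str | Path | None = None,
               ) -> tuple[FragmentLibrary, dict]:
    """Search one target complex against a database of complexes.

    ``target`` is a MolecularComplex or a (receptor_path, ligand_path)
    pair; ``database`` is a directory path or a list of MolecularComplex.
    Failures on individual database entries are logged and skipped. Returns
    the assembled fragment library and a per-complex match dict; when
    ``out_dir`` is given also writes fragment files, a match TSV, the
    manifest and a run-metadata file.
    """
    config = config or SearchConfig()
    if isinstance(target, MolecularComplex):
        target_cx = target
    else:
        receptor_path, ligand_path = target
        target_cx = read_complex(receptor_path, ligand_path,
                                 include_waters=config.include_waters)

    target_graph = build_interface_graph(
        target_cx, cutoff=config.cutoff, epsilon=config.epsilon,
        include_waters=config.include_waters, seed=config.seed,
        n_replicates=config.ad_replicates)
    params = config.match_params()
    patterns = grow_patterns(target_graph, params)
    logger.info("%s: %d interfacial receptor atoms, %d patterns",
                target_cx.complex_id,
                len(target_graph.interfacial_receptor_nodes), len(patterns))

    if isinstance(database, (str, Path)):
        entries = discover_database(database)
        loader = lambda e: (e[0], read_complex(  # noqa: E731
            e[1], e[2], include_waters=config.include_waters, complex_id=e[0]))
    else:
        entries = list(database)
        loader = lambda cx: (cx.complex_id, cx)  # noqa: E731

    fragments = []
    all_matches: dict[str, list] = {}
    skipped: list[tuple[str, str]] = []
    for entry in entries:
        t0 = time.perf_counter()
        try:
            cid, db_cx = loader(entry)
            db_graph = build_interface_graph(
                db_cx, cutoff=config.cutoff, epsilon=config.epsilon,
                include_waters=config.include_waters, seed=config.seed,
                n_replicates=config.ad_replicates)
            matches = find_matches(target_graph, db_graph, params,
                                   patterns=patterns)
            all_matches[cid] = matches
            for k, match in enumerate(matches):
                frag = extract_fragment(db_cx, db_graph, match, target_cx,
                                        safety_distance=config.safety_distance,
                                        match_index=k)
                if frag is not None:
                    fragments.append(frag)
            logger.info("%s: %d matches, %d fragments so far (%.2f s)", cid,
                        len(matches), len(fragments),
                        time.perf_counter() - t0)
        except Exception as exc:  # robustness: one bad entry never aborts
            name = entry if isinstance(entry, str) else (
                entry.complex_id if isinstance(entry, MolecularComplex)
                else entry[0])
            logger.warning("skipping database entry %s: %s", name, exc)
            skipped.append((str(name), str(exc)))
            continue

    library = assemble_library(fragments, target_cx.complex_id,
                               params=asdict(config))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fragments(library, out_dir, format="mol2")
        flat = [m for cid in sorted(all_matches) for m in all_matches[cid]]
        write_match_tsv(flat, out_dir / "matches.tsv")
        config.save(out_dir / "run_config.txt")
        metadata = {
            "fragvlib_version": __version__,
            "target": target_cx.complex_id,
            "n_database_entries": len(entries),
            "n_skipped": len(skipped),
            "skipped": skipped,
            "n_matches": sum(len(v) for v in all_matches.values()),
            "n_fragments": len(library.fragments),
            "config": asdict(config),
        }
        (out_dir / "run_metadata.json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return library, all_matches
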