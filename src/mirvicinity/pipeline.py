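"""End-to-end orchestration: filter, extract, census, motif scan, 3D compare.

Every stage is a pure function of (inputs, config, seed); the report bundle is
a directory of TSV/FASTA files plus a JSON run manifest echoing the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .dataset_prep import (
    build_vicinity_sets,
    filter_by_flank,
    filter_report_to_tsv,
    qualifying_loci,
    vicinity_to_fasta,
)
from .io_formats import (
    FormatError,
    PairTable,
    PrecursorRecord,
    parse_ct,
    parse_dotbracket_file,
    parse_pdb_fragment,
    parse_precursor_table,
)
from .motif_seeker import (
    find_motifs_all_loci,
    per_phylum_summary,
    summarize_motifs,
)
from .seq_patterns import pattern_census, position_frequency_table
from .struct3d import align_set, ermsd_set, summarize_distances

logger = logging.getLogger(__name__)

FRAGMENT_PDB_ATOMS = ("P", "C1'", "C2", "C4", "C6")


@dataclass
class PipelineConfig:
    fasta: str = "precursors.fasta"
    annotation: str = "annotation.tsv"
    structures_dir: str | None = "structures"
    pdb_dir: str | None = None
    report_dir: str = "reports"
    min_flank_large: int = 8
    min_flank_small: int = 4
    flank_large: int = 8
    flank_small: int = 4
    window: int = 4
    pattern_k: tuple[int, ...] = (8, 4)
    reference_index: int = 0
    atom_subset: tuple[str, ...] = FRAGMENT_PDB_ATOMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if min(self.flank_large, self.flank_small) < self.window:
            raise ValueError("vicinity flanks must be >= the motif window")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for name in ("pattern_k", "atom_subset"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _load_structures(
    structures_dir: Path, records: Sequence[PrecursorRecord]
) -> dict[str, PairTable]:
    """Read one structure per precursor id from .db/.dotbracket/.ct files."""
    by_id: dict[str, PairTable] = {}
    known = {rec.id for rec in records}
    for path in sorted(structures_dir.iterdir()):
        if path.suffix in (".db", ".dotbracket"):
            for sid, pt in parse_dotbracket_file(path.read_text()):
                name = sid if sid in known else path.stem
                by_id[name] = pt
        elif path.suffix == ".ct":
            _, pt = parse_ct(path.read_text())
            by_id[path.stem] = pt
    return by_id


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage the inputs allow; return the report directory."""
    report_dir = Path(config.report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)

    try:
        records = parse_precursor_table(
            Path(config.fasta).read_text(), Path(config.annotation).read_text()
        )
    except (OSError, FormatError, ValueError) as exc:
        raise RuntimeError(f"stage 'prepare' failed: {exc}") from exc
    logger.info("prepare: %d precursor records", len(records))

    # --- sequence level -----------------------------------------------------
    for tag, min_flank, flank in (
        ("large", config.min_flank_large, config.flank_large),
        ("small", config.min_flank_small, config.flank_small),
    ):
        report = filter_by_flank(records, min_flank)
        logger.info("filter(min_flank=%d): kept %d, dropped %d",
                    min_flank, len(report.kept), len(report.dropped))
        (report_dir / f"filter_{tag}.tsv").write_text(filter_report_to_tsv(report))
        up, down = build_vicinity_sets(report, flank)
        (report_dir / f"vicinity_{tag}_5p.fasta").write_text(vicinity_to_fasta(up))
        (report_dir / f"vicinity_{tag}_3p.fasta").write_text(vicinity_to_fasta(down))
        if up:
            for side, vs in (("5p", up), ("3p", down)):
                table = position_frequency_table(vs, flank)
                (report_dir / f"frequency_{tag}_{side}.tsv").write_text(table.to_tsv())
            census = pattern_census(up, down, flank)
            (report_dir / f"pattern_census_k{flank}.tsv").write_text(census.to_tsv())

    # --- secondary structure level -----------------------------------------
    structures: dict[str, PairTable] = {}
    if config.structures_dir and Path(config.structures_dir).is_dir():
        structures = _load_structures(Path(config.structures_dir), records)
    if structures:
        per_structure = []
        per_structure_phylum = []
        motif_rows = ["id\tlabel\tside\tdistance\tpositions5\tpositions3"]
        analyzed = 0
        for rec in records:
            pt = structures.get(rec.id)
            if pt is None:
                continue
            if pt.length != len(rec.sequence):
                raise RuntimeError(
                    f"stage 'motifs' failed: structure length {pt.length} != sequence "
                    f"length {len(rec.sequence)} for record {rec.id!r}"
                )
            analyzed += 1
            loci = [rec.loci[i] for i in qualifying_loci(rec, config.window)]
            motifs = find_motifs_all_loci(pt, loci, config.window, structure_id=rec.id)
            per_structure.append((rec.id, motifs))
            per_structure_phylum.append((rec.id, rec.phylum, motifs))
            for m in motifs:
                motif_rows.append(
                    f"{rec.id}\t{m.label}\t{m.side}\t{m.distance}"
                    f"\t{','.join(map(str, m.positions5))}\t{','.join(map(str, m.positions3))}"
                )
        summary = summarize_motifs(per_structure, analyzed)
        (report_dir / "motifs_per_structure.tsv").write_text("\n".join(motif_rows) + "\n")
        (report_dir / "motif_summary.tsv").write_text(summary.to_tsv())
        totals = {}
        for _, phylum, _m in per_structure_phylum:
            totals[phylum] = totals.get(phylum, 0) + 1
        phylum_tsv = ["phylum\tlabel\tdistance\tmotif_count\tstructures_with_motif\tpercent"]
        for phylum, psum in sorted(per_phylum_summary(per_structure_phylum, totals).items()):
            for row in psum.table.itertuples(index=False):
                phylum_tsv.append(
                    f"{phylum}\t{row.label}\t{row.distance}\t{row.motif_count}"
                    f"\t{row.structures_with_motif}\t{row.percent:.2f}"
                )
        (report_dir / "motif_summary_by_phylum.tsv").write_text("\n".join(phylum_tsv) + "\n")
        logger.info("motifs: %d structures analyzed", analyzed)
    else:
        logger.warning("no secondary structures found; sequence-level reports only")

    # --- tertiary structure level ------------------------------------------
    if config.pdb_dir and Path(config.pdb_dir).is_dir():
        _run_3d_stage(config, records, report_dir)

    manifest = {
        "package": "mirvicinity",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    (report_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report_dir


def _run_3d_stage(
    config: PipelineConfig, records: Sequence[PrecursorRecord], report_dir: Path
) -> None:
    """Group PDB models by phylum subdirectory, align within groups."""
    pdb_dir = Path(config.pdb_dir)
    groups: dict[str, list] = {}
    for sub in sorted(p for p in pdb_dir.iterdir() if p.is_dir()):
        frags = []
        for path in sorted(sub.glob("*.pdb")):
            text = path.read_text()
            # entire model; residue range spans whatever the file contains
            numbers = [int(line[22:26]) for line in text.splitlines()
                       if line.startswith("ATOM")]
            frag = parse_pdb_fragment(
                text, "A", (min(numbers), max(numbers)), config.atom_subset
            )
            frags.append(frag)
        if len(frags) >= 2:
            groups[sub.name] = frags
    if not groups:
        logger.warning("PDB directory %s holds no comparable groups", pdb_dir)
        return
    rmsd_groups, ermsd_groups = {}, {}
    rows = ["group\tfragment\trmsd\termsd"]
    for name, frags in groups.items():
        ref = config.reference_index % len(frags)
        sups = align_set(frags, ref)
        erms = ermsd_set(frags, ref)
        rmsd_groups[name] = [s.rmsd for s in sups]
        ermsd_groups[name] = [e.ermsd for e in erms]
        others = [i for i in range(len(frags)) if i != ref]
        for idx, s, e in zip(others, sups, erms):
            rows.append(f"{name}\t{idx}\t{s.rmsd:.3f}\t{e.ermsd:.3f}")
    (report_dir / "distances_3d.tsv").write_text("\n".join(rows) + "\n")
    (report_dir / "rmsd_summary.tsv").write_text(
        summarize_distances(rmsd_groups).to_csv(sep="\t", index=False)
    )
    (report_dir / "ermsd_summary.tsv").write_text(
        summarize_distances(ermsd_groups).to_csv(sep="\t", index=False)
    )
    logger.info("compare3d: %d groups", len(groups))
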