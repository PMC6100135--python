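"""Synthetic inputs with ground truth: hairpin precursors with planted motifs,
composition-controlled vicinity sequences, and 3D fragment pairs.

The precursor generator builds a single hairpin from the inside out — terminal
loop, miRNA:miRNA* duplex (fully paired), a vicinity region on each side where
the requested bulges/internal loops are realized as unpaired positions, and a
basal stem — then samples a sequence whose paired positions are Watson-Crick
complementary (G-U wobble with a configurable probability).  Both arms are
annotated with exact coordinates and the returned motif list is the planted
truth, in the same form the detector reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .dataset_prep import SIDES, VicinitySeq
from .io_formats import (
    Fragment3D,
    MiRNALocus,
    PairTable,
    PrecursorRecord,
    Residue3D,
    parse_dotbracket,
    to_dotbracket,
    write_ct,
    write_pdb_fragment,
)
from .motif_seeker import StructureMotif, _SIDE_ORDER

BASES = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class PlantedMotif:
    """A motif to realize in the vicinity: n unpaired on the strand entered
    from the miRNA, m on the opposing strand, at distance D from the miRNA."""

    kind: str  # "internal_loop" | "bulge"
    n: int
    m: int
    side: str  # "upstream" | "downstream"
    distance: int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.n + self.m < 1 or self.n < 0 or self.m < 0:
            raise ValueError("motif sizes must be non-negative with n + m >= 1")
        is_bulge = (self.n == 0) != (self.m == 0)
        if (self.kind == "bulge") != is_bulge:
            raise ValueError(f"kind {self.kind!r} inconsistent with sizes {self.n}-{self.m}")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def walked_span(self) -> range:
        """Walked-strand distance slots this motif occupies."""
        return range(self.distance, self.distance + max(self.n, 1))


@dataclass(frozen=True)
class PrecursorSpec:
    duplex_len: int = 8
    terminal_loop_len: int = 6
    basal_stem_len: int = 3
    planted: tuple[PlantedMotif, ...] = ()
    composition: Sequence[float] | None = None  # global A,C,G,U probabilities
    seed: int = 0
    window: int = 4
    gu_prob: float = 0.1
    record_id: str = "syn-MIR0001"
    species: str = "synthetic"
    phylum: str = "Synthetica"

    def __post_init__(self) -> None:
        if min(self.duplex_len, self.terminal_loop_len, self.basal_stem_len) < 1:
            raise ValueError("duplex, terminal loop and basal stem lengths must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for side in SIDES:
            motifs = [p for p in self.planted if p.side == side]
            occupied: set[int] = set()
            for p in motifs:
                if p.distance > self.window:
                    raise ValueError(
                        f"planted motif at distance {p.distance} exceeds window {self.window}"
                    )
                span = set(p.walked_span)
                if span & occupied:
                    raise ValueError(f"planted motifs overlap on the {side} side")
                occupied |= span


def _side_columns(motifs: list[PlantedMotif], guard: bool) -> list[object]:
    """Column layout of one vicinity side, in outward (distance) order.

    Columns are "P" (a base pair) or a PlantedMotif.  A 0-m bulge occupies
    one paired column at its distance, with the opposing gap attached.  The
    downstream side gets a guard pair after the outermost motif so a closing
    pair separates it from the terminal loop; upstream, the basal stem closes.
    """
    cols: list[object] = []
    d = 1
    for mot in sorted(motifs, key=lambda p: p.distance):
        while d < mot.distance:
            cols.append("P")
            d += 1
        cols.append(mot)
        d += max(mot.n, 1)
    if motifs and guard:
        cols.append("P")
    return cols


def simulate_precursor(
    spec: PrecursorSpec,
) -> tuple[PrecursorRecord, PairTable, list[StructureMotif]]:
    """Build one hairpin precursor realizing the planted motif list exactly.

    Returns the annotated record (both arms), its ground-truth pair table,
    and the planted motifs as :class:`StructureMotif` objects with the exact
    member positions, ordered as the detector orders its output.
    """
    up = [p for p in spec.planted if p.side == "upstream"]
    down = [p for p in spec.planted if p.side == "downstream"]
    cols_up = _side_columns(up, guard=False)
    cols_down = _side_columns(down, guard=True)

    chars: list[str] = []
    walked: dict[PlantedMotif, list[int]] = {p: [] for p in spec.planted}
    opposing: dict[PlantedMotif, list[int]] = {p: [] for p in spec.planted}

    def emit(text: str, motif: PlantedMotif | None = None, opp: bool = False) -> None:
        start = len(chars) + 1
        chars.extend(text)
        if motif is not None and text.strip("."):
            raise AssertionError("motif columns emit only unpaired positions")
        if motif is not None:
            bucket = opposing[motif] if opp else walked[motif]
            bucket.extend(range(start, start + len(text)))

    # 5' half
    emit("(" * spec.basal_stem_len)
    for col in reversed(cols_up):
        if col == "P":
            emit("(")
        elif col.n == 0:
            emit("(")  # opposing-strand bulge: walked column stays paired
        else:
            emit("." * col.n, motif=col)
    duplex5_start = len(chars) + 1
    emit("(" * spec.duplex_len)
    duplex5_end = len(chars)
    for col in cols_down:
        if col == "P":
            emit("(")
        elif col.n == 0:
            emit("(")
        else:
            emit("." * col.n, motif=col)
    emit("." * spec.terminal_loop_len)
    # 3' half (mirror)
    for col in reversed(cols_down):
        if col == "P":
            emit(")")
        elif col.n == 0:
            emit(")")
            emit("." * col.m, motif=col, opp=True)
        else:
            emit("." * col.m, motif=col, opp=True)
    duplex3_start = len(chars) + 1
    emit(")" * spec.duplex_len)
    duplex3_end = len(chars)
    for col in cols_up:
        if col == "P":
            emit(")")
        elif col.n == 0:
            emit("." * col.m, motif=col, opp=True)
            emit(")")
        else:
            emit("." * col.m, motif=col, opp=True)
    emit(")" * spec.basal_stem_len)

    db = "".join(chars)
    pt = parse_dotbracket(db)

    rng = np.random.default_rng(spec.seed)
    probs = (np.full(4, 0.25) if spec.composition is None
             else np.asarray(spec.composition, dtype=float))
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("composition must be 4 probabilities summing to 1")
    seq = [""] * pt.length
    for i in range(1, pt.length + 1):
        j = int(pt.partner[i])
        if j == 0:
            seq[i - 1] = BASES[rng.choice(4, p=probs)]
        elif j > i:
            b = BASES[rng.choice(4, p=probs)]
            partner = _WC[b]
            if b in _WOBBLE and rng.random() < spec.gu_prob:
                partner = _WOBBLE[b]
            seq[i - 1], seq[j - 1] = b, partner
    sequence = "".join(seq)

    loci = (
        MiRNALocus(duplex5_start, duplex5_end, "five_prime", "experimental"),
        MiRNALocus(duplex3_start, duplex3_end, "three_prime", "by_similarity"),
    )
    record = PrecursorRecord(spec.record_id, sequence, loci, spec.species, spec.phylum)

    truth = [
        StructureMotif(
            kind=p.kind, size5=p.n, size3=p.m, side=p.side, distance=p.distance,
            positions5=tuple(sorted(walked[p])), positions3=tuple(sorted(opposing[p])),
        )
        for p in spec.planted
    ]
    truth.sort(key=lambda m: (_SIDE_ORDER[m.side], m.distance))
    return record, pt, truth


def simulate_vicinity_set(
    n: int,
    flank_len: int,
    composition: np.ndarray | Sequence[Sequence[float]] | None,
    seed: int,
) -> list[VicinitySeq]:
    """Sample n vicinity sequences, positions independent.

    ``composition`` is a (flank_len, 4) row-stochastic matrix over A,C,G,U
    (a single length-4 vector is broadcast; None means uniform).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if composition is None:
        comp = np.full((flank_len, 4), 0.25)
    else:
        comp = np.asarray(composition, dtype=float)
        if comp.ndim == 1:
            comp = np.tile(comp, (flank_len, 1))
    if comp.shape != (flank_len, 4):
        raise ValueError(f"composition must have shape ({flank_len}, 4), got {comp.shape}")
    if not np.allclose(comp.sum(axis=1), 1.0):
        raise ValueError("composition rows must sum to 1")
    if np.any(comp < 0):
        raise ValueError("composition probabilities must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = "".join(BASES[rng.choice(4, p=comp[p])] for p in range(flank_len))
        out.append(VicinitySeq(f"sim{i:05d}", 0, "upstream", seq, flank_len))
    return out


# ---------------------------------------------------------------------------
# 3D fragments
# ---------------------------------------------------------------------------

#: simplified residue template: phosphate, C1' and the three base-frame ring
#: atoms, in a local frame with the helix axis along z (A-form-like scale)
_RESIDUE_TEMPLATE = {
    "P": np.array([9.0, -3.0, 1.0]),
    "C1'": np.array([9.4, 0.0, 0.0]),
    "C2": np.array([6.5, 0.8, 0.2]),
    "C4": np.array([4.3, 0.0, 0.1]),
    "C6": np.array([5.9, -1.6, 0.0]),
}
FRAGMENT_ATOMS = ("P", "C1'", "C2", "C4", "C6")
_HELIX_TWIST = np.deg2rad(32.7)
_HELIX_RISE = 2.81


@dataclass(frozen=True)
class FragmentSpec:
    n_residues: int = 8
    geometry: str = "ideal_helix"  # "ideal_helix" | "random_coil"
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.geometry not in ("ideal_helix", "random_coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _base_fragment(spec: FragmentSpec, rng: np.random.Generator) -> Fragment3D:
    residues = []
    origin = np.zeros(3)
    for i in range(spec.n_residues):
        if spec.geometry == "ideal_helix":
            rot = _rotz(i * _HELIX_TWIST)
            shift = np.array([0.0, 0.0, i * _HELIX_RISE])
        else:
            rot = _random_rotation(rng)
            if i > 0:
                step = rng.normal(size=3)
                origin = origin + 6.0 * step / np.linalg.norm(step)
            shift = origin
        atoms = {name: rot @ xyz + shift for name, xyz in _RESIDUE_TEMPLATE.items()}
        residues.append(Residue3D(i + 1, BASES[i % 4], atoms))
    return Fragment3D(tuple(residues), FRAGMENT_ATOMS)


def _perturbed_copy(
    base: Fragment3D, sigma: float, rng: np.random.Generator
) -> Fragment3D:
    rot = _random_rotation(rng)
    trans = rng.uniform(-10.0, 10.0, size=3)
    residues = []
    for res in base.residues:
        atoms = {
            name: rot @ np.asarray(xyz) + trans + rng.normal(0.0, sigma, size=3)
            for name, xyz in res.atoms.items()
        }
        residues.append(Residue3D(res.number, res.base, atoms))
    return Fragment3D(tuple(residues), base.atom_subset)


def simulate_fragment_pair(spec: FragmentSpec) -> tuple[Fragment3D, Fragment3D]:
    """A fragment and a rigidly moved copy with Gaussian coordinate noise."""
    rng = np.random.default_rng(spec.seed)
    base = _base_fragment(spec, rng)
    return base, _perturbed_copy(base, spec.noise_sigma, rng)


def simulate_fragment_set(n_fragments: int, spec: FragmentSpec) -> list[Fragment3D]:
    """One base fragment plus n-1 rigidly moved noisy copies (a 'phylum' group)."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(spec.seed)
    base = _base_fragment(spec, rng)
    return [base] + [
        _perturbed_copy(base, spec.noise_sigma, rng) for _ in range(n_fragments - 1)
    ]


# ---------------------------------------------------------------------------
# Bundle writer: the same files the pipeline consumes
# ---------------------------------------------------------------------------

def write_bundle(
    specs: Sequence[PrecursorSpec],
    outdir: str | Path,
    *,
    structure_format: str = "dotbracket",
) -> Path:
    """Emit FASTA + annotation TSV + one structure file per record.

    Returns the output directory.  Structure files go to ``structures/`` as
    dot-bracket (.db) or CT (.ct); the planted truth is written to
    ``truth_motifs.tsv`` for end-to-end checks.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    fasta_lines: list[str] = []
    ann_lines = ["id\tstart\tend\tarm\tevidence\tspecies\tphylum"]
    truth_lines = ["id\tlabel\tside\tdistance\tpositions5\tpositions3"]
    for spec in specs:
        record, pt, truth = simulate_precursor(spec)
        fasta_lines.append(f">{record.id}\n{record.sequence}")
        for locus in record.loci:
            ann_lines.append(
                f"{record.id}\t{locus.start}\t{locus.end}\t{locus.arm}\t{locus.evidence}"
                f"\t{record.species}\t{record.phylum}"
            )
        if structure_format == "ct":
            (outdir / "structures" / f"{record.id}.ct").write_text(
                write_ct(record.sequence, pt, title=record.id)
            )
        else:
            (outdir / "structures" / f"{record.id}.db").write_text(
                f">{record.id}\n{record.sequence}\n{to_dotbracket(pt)}\n"
            )
        for m in truth:
            truth_lines.append(
                f"{record.id}\t{m.label}\t{m.side}\t{m.distance}"
                f"\t{','.join(map(str, m.positions5))}\t{','.join(map(str, m.positions3))}"
            )
    (outdir / "precursors.fasta").write_text("\n".join(fasta_lines) + "\n")
    (outdir / "annotation.tsv").write_text("\n".join(ann_lines) + "\n")
    (outdir / "truth_motifs.tsv").write_text("\n".join(truth_lines) + "\n")
    return outdir


def write_fragment_bundle(
    groups: dict[str, Sequence[Fragment3D]], outdir: str | Path
) -> Path:
    """Write each group's fragments as PDB files under ``pdb/<group>/``."""
    outdir = Path(outdir)
    for group, fragments in groups.items():
        gdir = outdir / "pdb" / group
        gdir.mkdir(parents=True, exist_ok=True)
        for i, frag in enumerate(fragments):
            (gdir / f"fragment_{i:02d}.pdb").write_text(write_pdb_fragment(frag))
    return outdir
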