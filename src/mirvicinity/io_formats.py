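"""Readers and writers for the formats the pipeline touches.

FASTA and a tab-separated miRNA annotation table describe precursor records;
dot-bracket and CT (Connect) files carry secondary structures; PDB ATOM records
carry 3D fragment coordinates.  All coordinates are 1-based inclusive, matching
the miRBase and CT conventions; dot-bracket position ``i`` maps to sequence
position ``i``.

Sequences are normalized at parse time: lowercase is folded to uppercase and T
to U.  Any character outside {A, C, G, U} after normalization is a hard error —
the downstream analysis alphabet has no N.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

ARMS = ("five_prime", "three_prime", "unknown")
EVIDENCE_CLASSES = ("experimental", "by_similarity", "not_experimental")

#: base-frame atoms used for eRMSD-style comparisons (present in all four bases)
BASE_FRAME_ATOMS = ("C2", "C4", "C6")

_DNA_TO_RNA = str.maketrans("acgut", "ACGUU")
_RNA_ALPHABET = frozenset("ACGU")

#: bracket families: "()" is the nested layer, the rest are pseudoknot layers
_OPENERS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


class FormatError(ValueError):
    """Malformed input file or record."""


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, T->U; reject anything outside {A,C,G,U} with its position."""
    seq = raw.translate(_DNA_TO_RNA).upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _RNA_ALPHABET:
            raise FormatError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos} "
                "(alphabet is A/C/G/U, T accepted as U)"
            )
    return seq


# ---------------------------------------------------------------------------
# Precursor records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiRNALocus:
    """One mature miRNA annotated on a precursor (1-based inclusive)."""

    start: int
    end: int
    arm: str = "unknown"
    evidence: str = "not_experimental"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid locus [{self.start},{self.end}]")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.evidence not in EVIDENCE_CLASSES:
            raise ValueError(
                f"unknown evidence {self.evidence!r}; expected one of {EVIDENCE_CLASSES}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA sequence with its annotated miRNA loci and taxonomy."""

    id: str
    sequence: str
    loci: tuple[MiRNALocus, ...]
    species: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for locus in self.loci:
            if locus.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: locus [{locus.start},{locus.end}] outside "
                    f"sequence of length {len(self.sequence)}"
                )
        spans = sorted((l.start, l.end) for l in self.loci)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"record {self.id!r}: loci overlap ({s1}-{e1} and {s2}-{e2})")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_precursor_table(
    fasta_source: TextIO | str,
    annotation_source: TextIO | str,
) -> list[PrecursorRecord]:
    """Join a multi-FASTA with an annotation TSV into precursor records.

    The annotation table needs columns ``id, start, end, arm, evidence,
    species, phylum`` (header row required).  Every annotation id must have a
    FASTA entry and vice versa.  Output order follows the FASTA; loci are
    sorted by start, so the result is insensitive to row order in either input.
    """
    if isinstance(fasta_source, str):
        fasta_source = io.StringIO(fasta_source)
    if isinstance(annotation_source, str):
        annotation_source = io.StringIO(annotation_source)

    table = pd.read_csv(annotation_source, sep="\t", dtype=str)
    required = {"id", "start", "end", "arm", "evidence", "species", "phylum"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")

    loci_by_id: dict[str, list[MiRNALocus]] = {}
    meta_by_id: dict[str, tuple[str, str]] = {}
    for row in table.itertuples(index=False):
        loci_by_id.setdefault(row.id, []).append(
            MiRNALocus(int(row.start), int(row.end), row.arm, row.evidence)
        )
        meta_by_id[row.id] = (str(row.species), str(row.phylum))

    records: list[PrecursorRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(fasta_source, "fasta"):
        seq = normalize_sequence(str(entry.seq), record_id=entry.id)
        if entry.id not in loci_by_id:
            raise FormatError(f"FASTA entry {entry.id!r} has no annotation rows")
        species, phylum = meta_by_id[entry.id]
        loci = tuple(sorted(loci_by_id[entry.id], key=lambda l: l.start))
        records.append(PrecursorRecord(entry.id, seq, loci, species, phylum))
        seen.add(entry.id)

    orphans = set(loci_by_id) - seen
    if orphans:
        raise FormatError(f"annotation ids with no FASTA entry: {sorted(orphans)}")
    return records


# ---------------------------------------------------------------------------
# Secondary structure: pair tables, dot-bracket, CT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTable:
    """Secondary structure as a 1-based partner-index array.

    ``partner[i] == j`` when i pairs j in the nested layer, 0 when unpaired.
    Pairs from non-"()" bracket families are kept in ``pseudoknots`` and left
    unpaired in ``partner`` — motif analysis works on the nested layer only.
    """

    partner: np.ndarray  # int array, index 0 unused
    pseudoknots: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.partner, dtype=int)
        object.__setattr__(self, "partner", p)
        n = len(p) - 1
        for i in range(1, n + 1):
            j = p[i]
            if j == 0:
                continue
            if j == i:
                raise FormatError(f"position {i} pairs itself")
            if not (1 <= j <= n) or p[j] != i:
                raise FormatError(f"asymmetric pair table: {i} -> {j} but {j} -> {p[j] if 1 <= j <= n else '?'}")

    @property
    def length(self) -> int:
        return len(self.partner) - 1

    def pairs(self) -> list[tuple[int, int]]:
        """Nested-layer pairs (i, j) with i < j."""
        return [(i, int(self.partner[i])) for i in range(1, self.length + 1)
                if self.partner[i] > i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairTable):
            return NotImplemented
        return (np.array_equal(self.partner, other.partner)
                and self.pseudoknots == other.pseudoknots)

    def __hash__(self) -> int:  # frozen dataclass with ndarray
        return hash((self.partner.tobytes(), self.pseudoknots))


def pairs_to_table(n: int, pairs: Iterable[tuple[int, int]],
                   pseudoknots: Iterable[tuple[int, int]] = ()) -> PairTable:
    partner = np.zeros(n + 1, dtype=int)
    for i, j in pairs:
        partner[i], partner[j] = j, i
    return PairTable(partner, tuple(tuple(p) for p in pseudoknots))


def parse_dotbracket(line: str) -> PairTable:
    """Parse one dot-bracket string into a :class:`PairTable`.

    "()" forms the nested layer; "[]", "{}", "<>" and upper/lowercase letter
    pairs (Aa, Bb, ...) are recorded as pseudoknot pairs.
    """
    line = line.strip()
    n = len(line)
    partner = np.zeros(n + 1, dtype=int)
    stacks: dict[str, list[int]] = {}
    pseudo: list[tuple[int, int]] = []
    for pos, ch in enumerate(line, start=1):
        if ch == ".":
            continue
        if ch in _OPENERS or ch.isupper():
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSERS or ch.islower():
            opener = _CLOSERS.get(ch, ch.upper())
            stack = stacks.get(opener, [])
            if not stack:
                raise FormatError(f"unbalanced bracket {ch!r} at position {pos}")
            i = stack.pop()
            if opener == "(":
                partner[i], partner[pos] = pos, i
            else:
                pseudo.append((i, pos))
        else:
            raise FormatError(f"invalid structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(f"unbalanced bracket {opener!r} at position {stack[0]}")
    return PairTable(partner, tuple(sorted(pseudo)))


def parse_dotbracket_file(source: TextIO | str) -> list[tuple[str, PairTable]]:
    """Parse a dot-bracket file with optional ">id" lines.

    Lines over the structure alphabet become structures; sequence lines (pure
    ACGUT) under an id are skipped, matching common prediction-tool output.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    out: list[tuple[str, PairTable]] = []
    current_id = ""
    idx = 0
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            current_id = line[1:].split()[0] if len(line) > 1 else ""
            continue
        if set(line.upper()) <= (_RNA_ALPHABET | {"T", "N"}):
            continue  # sequence line
        idx += 1
        out.append((current_id or f"structure_{idx}", parse_dotbracket(line)))
    return out


def parse_ct(source: TextIO | str) -> tuple[str, PairTable]:
    """Parse a single-structure CT (Connect) file.

    Layout: a header line whose first token is the length (extra tokens are
    ignored), then one 6-column line per nucleotide: index, base, previous,
    next, pair index (0 = unpaired), original index.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = [ln for ln in (raw.strip() for raw in source) if ln]
    if not lines:
        raise FormatError("empty CT input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"bad CT header: {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) != n:
        raise FormatError(f"CT header declares {n} nucleotides but body has {len(body)} lines")
    partner = np.zeros(n + 1, dtype=int)
    bases: list[str] = []
    for ln in body:
        cols = ln.split()
        if len(cols) < 6:
            raise FormatError(f"CT body line has {len(cols)} columns, expected 6: {ln!r}")
        i, base, pair = int(cols[0]), cols[1], int(cols[4])
        if not (1 <= i <= n):
            raise FormatError(f"CT index {i} out of range 1..{n}")
        bases.append(base)
        partner[i] = pair
    seq = normalize_sequence("".join(bases), record_id="CT")
    try:
        pt = PairTable(partner)
    except FormatError as exc:
        raise FormatError(f"inconsistent CT pair column: {exc}") from exc
    return seq, pt


def write_ct(sequence: str, pt: PairTable, *, title: str = "") -> str:
    """Emit a 6-column CT file; inverse of :func:`parse_ct`."""
    n = len(sequence)
    if n != pt.length:
        raise FormatError(f"sequence length {n} != pair table length {pt.length}")
    header = f"{n} {title}".rstrip()
    lines = [header]
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else 0
        lines.append(f"{i} {sequence[i - 1]} {i - 1} {nxt} {int(pt.partner[i])} {i}")
    return "\n".join(lines) + "\n"


def to_dotbracket(pt: PairTable) -> str:
    """Dot-bracket string for the nested layer (pseudoknot layers as []/{}/<>)."""
    chars = ["."] * pt.length
    for i, j in pt.pairs():
        chars[i - 1], chars[j - 1] = "(", ")"
    families = "[{<"
    for idx, (i, j) in enumerate(pt.pseudoknots):
        fam = families[min(idx, 2)] if pt.pseudoknots else "["
        chars[i - 1] = fam
        chars[j - 1] = _OPENERS[fam]
    return "".join(chars)


# ---------------------------------------------------------------------------
# 3D fragments (PDB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue3D:
    number: int
    base: str
    atoms: dict[str, np.ndarray] = field(compare=False)


@dataclass(frozen=True)
class Fragment3D:
    """Ordered residue coordinate sets for a duplex-overlapping fragment."""

    residues: tuple[Residue3D, ...]
    atom_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        for res in self.residues:
            for name in self.atom_subset:
                if name not in res.atoms:
                    raise FormatError(f"residue {res.number} is missing atom {name!r}")
                xyz = np.asarray(res.atoms[name], dtype=float)
                if not np.all(np.isfinite(xyz)):
                    raise FormatError(f"residue {res.number} atom {name!r}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self, atom_names: Sequence[str] | None = None) -> np.ndarray:
        """(n_residues * n_atoms, 3) array, residues outer, atoms inner."""
        names = tuple(atom_names) if atom_names is not None else self.atom_subset
        rows = [np.asarray(res.atoms[name], dtype=float)
                for res in self.residues for name in names]
        return np.array(rows, dtype=float)

    def subset(self, atom_names: Sequence[str]) -> "Fragment3D":
        return Fragment3D(self.residues, tuple(atom_names))


def parse_pdb_fragment(
    source: TextIO | str,
    chain: str,
    residue_range: tuple[int, int],
    atom_subset: Sequence[str] = BASE_FRAME_ATOMS,
) -> Fragment3D:
    """Extract one residue range from PDB ATOM records.

    Residues come out in residue-number order with the requested atoms; for
    disordered atoms the first altloc occurrence is retained.  A requested atom
    missing from any selected residue is an error naming residue and atom.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("fragment", source)
    model = next(structure.get_models())
    if chain not in model:
        raise FormatError(f"chain {chain!r} not present in PDB input")
    lo, hi = residue_range
    residues: list[Residue3D] = []
    for res in model[chain]:
        num = res.id[1]
        if not (lo <= num <= hi):
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res.get_unpacked_list():
            if atom.get_name() in atoms:
                continue  # keep first altloc occurrence
            atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
        for name in atom_subset:
            if name not in atoms:
                raise FormatError(f"residue {num} ({res.get_resname().strip()}) is missing atom {name!r}")
        residues.append(Residue3D(num, res.get_resname().strip(), atoms))
    if not residues:
        raise FormatError(f"no residues in range {lo}..{hi} on chain {chain!r}")
    residues.sort(key=lambda r: r.number)
    return Fragment3D(tuple(residues), tuple(atom_subset))


def write_pdb_fragment(fragment: Fragment3D, chain: str = "A") -> str:
    """Serialize a fragment as minimal PDB ATOM records (subset writer)."""
    lines = []
    serial = 0
    for res in fragment.residues:
        for name in fragment.atom_subset:
            serial += 1
            x, y, z = np.asarray(res.atoms[name], dtype=float)
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:>5} {name:>4} {res.base:>3} {chain}{res.number:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
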