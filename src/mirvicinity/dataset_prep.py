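"""Flank filtering and vicinity-sequence extraction.

A precursor enters the analysis set for a given minimum flank only if at least
one of its miRNA loci is surrounded by that many nucleotides on both sides
(the S8/S4 style rule).  For every qualifying locus, two vicinity sequences
are read outward from the miRNA boundary: position 1 is always the nucleotide
adjacent to the miRNA, and positions increase moving away from it on both
sides, so "position 1" means the same thing upstream and downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import MiRNALocus, PrecursorRecord

SIDES = ("upstream", "downstream")


@dataclass(frozen=True)
class VicinitySeq:
    """A flank read in distance order (position 1 adjacent to the miRNA)."""

    precursor_id: str
    locus_index: int
    side: str
    seq: str
    flank_len: int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if len(self.seq) != self.flank_len:
            raise ValueError(
                f"vicinity sequence length {len(self.seq)} != flank_len {self.flank_len}"
            )

    @property
    def fasta_id(self) -> str:
        return f"{self.precursor_id}|{self.locus_index}|{self.side}|{self.flank_len}"


@dataclass(frozen=True)
class FilterReport:
    min_flank: int
    kept: tuple[PrecursorRecord, ...]
    dropped: tuple[tuple[str, str], ...]  # (id, reason)


def flank_lengths(rec: PrecursorRecord, locus: MiRNALocus) -> tuple[int, int]:
    """(upstream, downstream) flank sizes of a locus within its precursor."""
    if locus.end > len(rec.sequence):
        raise ValueError(f"locus [{locus.start},{locus.end}] outside record {rec.id!r}")
    return locus.start - 1, len(rec.sequence) - locus.end


def qualifying_loci(rec: PrecursorRecord, min_flank: int) -> list[int]:
    """Indices of loci with both flanks >= min_flank."""
    return [
        i for i, locus in enumerate(rec.loci)
        if min(flank_lengths(rec, locus)) >= min_flank
    ]


def filter_by_flank(records: Iterable[PrecursorRecord], min_flank: int) -> FilterReport:
    """Keep records where at least one locus has both flanks >= ``min_flank``."""
    if min_flank < 0:
        raise ValueError("min_flank must be >= 0")
    kept: list[PrecursorRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        if qualifying_loci(rec, min_flank):
            kept.append(rec)
        else:
            flanks = [flank_lengths(rec, locus) for locus in rec.loci]
            worst = max(flanks, key=min)
            dropped.append((rec.id, f"flank<{min_flank} (best locus flanks {worst})"))
    return FilterReport(min_flank, tuple(kept), tuple(dropped))


def extract_vicinity(
    rec: PrecursorRecord,
    locus: MiRNALocus,
    flank_len: int,
    side: str,
) -> VicinitySeq:
    """Read one flank outward from a miRNA boundary.

    Upstream: sequence positions start-1 down to start-flank_len, in that
    order.  Downstream: end+1 up to end+flank_len.  Either way the emitted
    string starts at the nucleotide touching the miRNA.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    up, down = flank_lengths(rec, locus)
    locus_index = rec.loci.index(locus) if locus in rec.loci else -1
    if side == "upstream":
        if up < flank_len:
            raise ValueError(
                f"record {rec.id!r} locus [{locus.start},{locus.end}]: upstream flank "
                f"{up} < {flank_len}"
            )
        positions = range(locus.start - 1, locus.start - 1 - flank_len, -1)
    else:
        if down < flank_len:
            raise ValueError(
                f"record {rec.id!r} locus [{locus.start},{locus.end}]: downstream flank "
                f"{down} < {flank_len}"
            )
        positions = range(locus.end + 1, locus.end + 1 + flank_len)
    seq = "".join(rec.sequence[p - 1] for p in positions)
    return VicinitySeq(rec.id, locus_index, side, seq, flank_len)


def build_vicinity_sets(
    report: FilterReport, flank_len: int
) -> tuple[list[VicinitySeq], list[VicinitySeq]]:
    """One (upstream, downstream) pair per qualifying locus of every kept record.

    Both returned lists always have equal cardinality: a locus contributes to
    neither or both sides.
    """
    upstream: list[VicinitySeq] = []
    downstream: list[VicinitySeq] = []
    for rec in report.kept:
        for idx in qualifying_loci(rec, flank_len):
            locus = rec.loci[idx]
            upstream.append(extract_vicinity(rec, locus, flank_len, "upstream"))
            downstream.append(extract_vicinity(rec, locus, flank_len, "downstream"))
    return upstream, downstream


def vicinity_to_fasta(vseqs: Sequence[VicinitySeq]) -> str:
    return "".join(f">{v.fasta_id}\n{v.seq}\n" for v in vseqs)


def filter_report_to_tsv(report: FilterReport) -> str:
    lines = ["id\tstatus\treason"]
    lines += [f"{rec.id}\tkept\t" for rec in report.kept]
    lines += [f"{rid}\tdropped\t{reason}" for rid, reason in report.dropped]
    return "\n".join(lines) + "\n"
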