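"""Detection of bulges and internal loops near the miRNA:miRNA* duplex.

From each boundary of an annotated miRNA locus the detector walks outward
along the nested secondary structure, up to ``window`` nucleotides (default
4).  It tracks the last helix pair closing toward the miRNA; an unpaired run
of length n on the walked strand, closed by the next helix pair, together with
the m unpaired nucleotides it faces on the opposing strand, is reported as an
n-m internal loop (symmetric when n = m) or as a bulge when exactly one of n,
m is zero.  The motif's distance D is the index of its unpaired nucleotide
nearest the miRNA, counted from the miRNA terminus (terminus + 1 => D = 1).

Hairpin (terminal) loops are never reported: a walk that crosses the loop end
of the stem stops there.  Multi-branch junctions inside the window stop the
walk on that side with a logged "junction" sentinel — the motif vocabulary is
two-stranded, so a junction is not a motif call.  Lonely pairs count as pairs
(prediction tools emit them) and terminate unpaired runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MiRNALocus, PairTable

logger = logging.getLogger(__name__)

_SIDE_ORDER = {"upstream": 0, "downstream": 1}


@dataclass(frozen=True)
class StructureMotif:
    """One detected bulge or internal loop.

    ``size5`` counts unpaired nucleotides on the strand entered from the
    miRNA (the walked strand); ``size3`` counts the opposing strand.
    ``positions5``/``positions3`` hold the member nucleotide positions
    (1-based, ascending) on those two strands.
    """

    kind: str  # "internal_loop" | "bulge"
    size5: int
    size3: int
    side: str  # "upstream" | "downstream"
    distance: int
    positions5: tuple[int, ...]
    positions3: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.size5 + self.size3 < 1:
            raise ValueError("motif must contain at least one unpaired nucleotide")
        is_bulge = (self.size5 == 0) != (self.size3 == 0)
        if (self.kind == "bulge") != is_bulge:
            raise ValueError(
                f"kind {self.kind!r} inconsistent with sizes {self.size5}-{self.size3}"
            )
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def symmetric(self) -> bool:
        return self.size5 == self.size3

    @property
    def label(self) -> str:
        """"1-1", "2-2", ... for internal loops; "bulge-n" for bulges."""
        if self.kind == "bulge":
            return f"bulge-{self.size5 + self.size3}"
        return f"{self.size5}-{self.size3}"

    @property
    def all_positions(self) -> frozenset[int]:
        return frozenset(self.positions5) | frozenset(self.positions3)


def _walk_side(
    pt: PairTable,
    locus: MiRNALocus,
    side: str,
    window: int,
    structure_id: str = "",
) -> list[StructureMotif]:
    partner = pt.partner
    n = pt.length
    if side == "upstream":
        d = -1
        boundary = locus.start - 1
        def dist(p: int) -> int:
            return locus.start - p
        scan = locus.start
    else:
        d = +1
        boundary = locus.end + 1
        def dist(p: int) -> int:
            return p - locus.end
        scan = locus.end

    # last pair closing toward the miRNA: nearest paired position at or
    # inside the boundary
    a = scan
    while locus.start <= a <= locus.end and partner[a] == 0:
        a -= d
    if not (locus.start <= a <= locus.end):
        logger.warning("%s: %s side of locus [%d,%d] has no anchoring pair; skipped",
                       structure_id or "structure", side, locus.start, locus.end)
        return []
    b = int(partner[a])

    def opposing_run(b_old: int, b_new: int) -> tuple[int, ...] | None:
        """Unpaired positions strictly between the old and new partners.

        None when any position in between is paired (multi-branch junction).
        """
        lo, hi = min(b_old, b_new), max(b_old, b_new)
        between = range(lo + 1, hi)
        if any(partner[q] != 0 for q in between):
            return None
        return tuple(between)

    def continues_helix(q: int, j2: int) -> bool:
        """True when pair (q, j2) extends the helix away from the miRNA.

        Orientation must be preserved (sign(j2 - q) == sign(b - a); a flip
        means the walk crossed the terminal loop) and the partner must move
        beyond the last partner in the walk's opposing direction.
        """
        if np.sign(j2 - q) != np.sign(b - a):
            return False
        return (j2 - b) * (-d) > 0

    motifs: list[StructureMotif] = []
    p = boundary
    while 1 <= p <= n and dist(p) <= window:
        if partner[p] != 0:
            j2 = int(partner[p])
            if not continues_helix(p, j2):
                # new pair does not continue the helix outward: junction
                # (or a sibling hairpin beyond a multiloop)
                logger.info("%s: junction at position %d (%s walk); side aborted",
                            structure_id or "structure", p, side)
                break
            opp = opposing_run(b, j2)
            if opp is None:
                logger.info("%s: junction opposite position %d (%s walk); side aborted",
                            structure_id or "structure", p, side)
                break
            if opp:
                motifs.append(StructureMotif(
                    kind="bulge", size5=0, size3=len(opp), side=side,
                    distance=dist(p), positions5=(), positions3=opp,
                ))
            a, b = p, j2
            p += d
            continue

        # unpaired run on the walked strand, starting at distance D
        run = [p]
        q = p + d
        while 1 <= q <= n and partner[q] == 0:
            run.append(q)
            q += d
        if not (1 <= q <= n):
            break  # ran off the molecule: exterior end, no closing pair
        j2 = int(partner[q])
        if not continues_helix(q, j2):
            # the pair (q, j2) spans the run when the walk crossed the stem's
            # terminal loop — excluded silently; otherwise it is a sibling
            # helix across a junction
            if not (min(q, j2) < run[0] < max(q, j2)):
                logger.info("%s: junction beyond unpaired run at %d (%s walk); side aborted",
                            structure_id or "structure", p, side)
            break
        opp = opposing_run(b, j2)
        if opp is None:
            logger.info("%s: junction beyond unpaired run at %d (%s walk); side aborted",
                        structure_id or "structure", p, side)
            break
        n_run, m_run = len(run), len(opp)
        motifs.append(StructureMotif(
            kind="internal_loop" if m_run >= 1 else "bulge",
            size5=n_run, size3=m_run, side=side, distance=dist(p),
            positions5=tuple(sorted(run)), positions3=opp,
        ))
        a, b = q, j2
        p = q + d
    return motifs


def find_motifs(
    pt: PairTable,
    locus: MiRNALocus,
    window: int = 4,
    *,
    structure_id: str = "",
) -> list[StructureMotif]:
    """All bulges/internal loops within ``window`` nt of one locus's boundaries.

    Output is deterministic, ordered by (side, distance) with upstream first.
    Motifs whose nearest unpaired nucleotide lies beyond the window are not
    reported.  Pseudoknot pairs are already absent from the nested layer of
    ``pt`` and therefore count as unpaired here.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (1 <= locus.start and locus.end <= pt.length):
        raise ValueError(
            f"locus [{locus.start},{locus.end}] outside structure of length {pt.length}"
        )
    motifs = []
    for side in ("upstream", "downstream"):
        motifs.extend(_walk_side(pt, locus, side, window, structure_id))
    motifs.sort(key=lambda m: (_SIDE_ORDER[m.side], m.distance))
    return motifs


def find_motifs_all_loci(
    pt: PairTable,
    loci: Sequence[MiRNALocus],
    window: int = 4,
    *,
    structure_id: str = "",
) -> list[StructureMotif]:
    """Motifs over all annotated loci with loop deduplication.

    When both the miRNA and miRNA* are annotated, each physical loop is seen
    from both strands (identical position sets).  It is counted once,
    attributed to the walk that reached its 5'-most unpaired nucleotide on the
    walked strand, so the result does not depend on which strand is called the
    miRNA.
    """
    by_positions: dict[frozenset[int], StructureMotif] = {}
    for locus in loci:
        for motif in find_motifs(pt, locus, window, structure_id=structure_id):
            key = motif.all_positions
            held = by_positions.get(key)
            if held is None:
                by_positions[key] = motif
                continue
            # prefer the occurrence whose walked strand holds the 5'-most
            # unpaired position of the loop
            target = min(key)
            if target in motif.positions5 and target not in held.positions5:
                by_positions[key] = motif
    out = list(by_positions.values())
    out.sort(key=lambda m: (_SIDE_ORDER[m.side], m.distance, min(m.all_positions)))
    return out


@dataclass(frozen=True)
class MotifSummary:
    """Per-(label, distance) motif and structure counts over a dataset."""

    table: pd.DataFrame
    # columns: label, distance, motif_count, structures_with_motif, percent
    total_structures: int

    def cell(self, label: str, distance: int) -> pd.Series:
        hit = self.table[(self.table.label == label) & (self.table.distance == distance)]
        if hit.empty:
            raise KeyError(f"no summary cell for motif {label!r} at distance {distance}")
        return hit.iloc[0]

    def percent(self, label: str, distance: int) -> float:
        if label not in set(self.table.label):
            raise KeyError(f"unknown motif label {label!r}")
        hit = self.table[(self.table.label == label) & (self.table.distance == distance)]
        return 0.0 if hit.empty else float(hit.iloc[0].percent)

    def to_tsv(self) -> str:
        from .seq_patterns import round_half_up
        out = self.table.copy()
        out["percent"] = out["percent"].map(lambda x: round_half_up(x, 2))
        return out.to_csv(sep="\t", index=False)


def summarize_motifs(
    per_structure: Iterable[tuple[str, Sequence[StructureMotif]]],
    total_structures: int,
) -> MotifSummary:
    """Tabulate motif counts and structures-with-at-least-one per (label, D).

    ``percent`` is structures_with_motif / total_structures * 100 — the
    denominator is the number of analyzed structures, not loci.
    """
    motif_count: dict[tuple[str, int], int] = {}
    structures: dict[tuple[str, int], set[str]] = {}
    seen_ids: set[str] = set()
    for sid, motifs in per_structure:
        seen_ids.add(sid)
        for m in motifs:
            key = (m.label, m.distance)
            motif_count[key] = motif_count.get(key, 0) + 1
            structures.setdefault(key, set()).add(sid)
    if total_structures < len(seen_ids):
        raise ValueError(
            f"total_structures={total_structures} < {len(seen_ids)} distinct structure ids"
        )
    rows = []
    for (label, dist), count in sorted(motif_count.items()):
        n_struct = len(structures[(label, dist)])
        rows.append({
            "label": label,
            "distance": dist,
            "motif_count": count,
            "structures_with_motif": n_struct,
            "percent": n_struct / total_structures * 100.0 if total_structures else 0.0,
        })
    columns = ["label", "distance", "motif_count", "structures_with_motif", "percent"]
    table = pd.DataFrame(rows, columns=columns)
    return MotifSummary(table, total_structures)


def summary_from_cell_counts(
    cells: Mapping[tuple[str, int], tuple[int, int]],
    total_structures: int,
) -> MotifSummary:
    """Build a summary directly from (motif_count, structures_with_motif) cells.

    Convenience for recomputing percentages from an already-tabulated census.
    """
    rows = []
    for (label, dist), (count, n_struct) in sorted(cells.items()):
        if n_struct > count:
            raise ValueError(f"cell {label}/D:{dist}: structures {n_struct} > motifs {count}")
        rows.append({
            "label": label,
            "distance": dist,
            "motif_count": count,
            "structures_with_motif": n_struct,
            "percent": n_struct / total_structures * 100.0 if total_structures else 0.0,
        })
    columns = ["label", "distance", "motif_count", "structures_with_motif", "percent"]
    return MotifSummary(pd.DataFrame(rows, columns=columns), total_structures)


def combined_percent(summary: MotifSummary, label: str, distances: Iterable[int]) -> float:
    """Sum of the per-distance structure percentages of one motif label.

    This is the additive convention used when quoting "motif X within the
    first k positions": cells are disjoint enough in practice that the sum is
    read as a coverage percentage.
    """
    distances = list(distances)
    if not distances:
        raise ValueError("distances must be non-empty")
    if label not in set(summary.table.label):
        raise KeyError(f"unknown motif label {label!r}")
    return float(sum(summary.percent(label, d) for d in distances))


def per_phylum_summary(
    per_structure: Iterable[tuple[str, str, Sequence[StructureMotif]]],
    totals_by_phylum: Mapping[str, int],
) -> dict[str, MotifSummary]:
    """Motif summaries split by phylum; input rows are (id, phylum, motifs)."""
    grouped: dict[str, list[tuple[str, Sequence[StructureMotif]]]] = {}
    for sid, phylum, motifs in per_structure:
        grouped.setdefault(phylum, []).append((sid, motifs))
    return {
        phylum: summarize_motifs(rows, totals_by_phylum.get(phylum, len(rows)))
        for phylum, rows in grouped.items()
    }
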