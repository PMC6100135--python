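"""Positional nucleotide frequencies and purine/pyrimidine pattern censuses.

The frequency table is the numeric equivalent of a probability-mode sequence
logo: raw per-position percentages with no small-sample correction, plus the
derived purine (R = A+G) and pyrimidine (Y = C+U) aggregates.  The pattern
census recodes each vicinity sequence over {R, Y} and counts all 2^k patterns,
read in distance order (first symbol = position adjacent to the miRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset_prep import VicinitySeq

BASES = ("A", "C", "G", "U")
_RY = str.maketrans("AGCU", "RRYY")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for report output (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_strings(vseqs: Iterable[VicinitySeq | str]) -> list[str]:
    return [v.seq if isinstance(v, VicinitySeq) else v for v in vseqs]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-position base percentages for a set of equal-length sequences."""

    n_seqs: int
    flank_len: int
    freq: pd.DataFrame  # index: position 1..flank_len; columns A C G U R Y (%)

    def to_tsv(self, ndigits: int = 2) -> str:
        out = self.freq.map(lambda x: round_half_up(x, ndigits))
        out.index.name = "position"
        return out.to_csv(sep="\t")


def position_frequency_table(
    vseqs: Sequence[VicinitySeq | str], flank_len: int
) -> FrequencyTable:
    """Count bases per position; percentages of the number of sequences.

    Full-precision values are kept internally (rows sum to exactly 100 up to
    float arithmetic); rounding happens only in report output.
    """
    seqs = _as_strings(vseqs)
    if not seqs:
        raise ValueError("cannot build a frequency table from an empty set")
    bad = [s for s in seqs if len(s) != flank_len]
    if bad:
        raise ValueError(
            f"{len(bad)} sequence(s) do not have length {flank_len} (e.g. {bad[0]!r})"
        )
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), flank_len)
    data = {b: (arr == b.encode()).sum(axis=0) / len(seqs) * 100.0 for b in BASES}
    frame = pd.DataFrame(data, index=pd.RangeIndex(1, flank_len + 1))
    frame["R"] = frame["A"] + frame["G"]
    frame["Y"] = frame["C"] + frame["U"]
    return FrequencyTable(len(seqs), flank_len, frame)


def recode_ry(seq: str) -> str:
    """A,G -> R (purine); C,U -> Y (pyrimidine)."""
    out = seq.translate(_RY)
    for pos, ch in enumerate(out, start=1):
        if ch not in "RY":
            raise ValueError(f"invalid character {seq[pos - 1]!r} at position {pos}")
    return out


@dataclass(frozen=True)
class PatternCensus:
    """Counts of every {R,Y}^k pattern in two vicinity subsets."""

    k: int
    table: pd.DataFrame
    # columns: pattern, count_up, count_down, pct_up, pct_down, pct_total

    @property
    def n_patterns(self) -> int:
        return len(self.table)

    def to_tsv(self, ndigits: int = 2) -> str:
        out = self.table.copy()
        for col in ("pct_up", "pct_down", "pct_total"):
            out[col] = out[col].map(lambda x: round_half_up(x, ndigits))
        return out.sort_values("pct_total", kind="stable").to_csv(sep="\t", index=False)


def pattern_census(
    upstream: Sequence[VicinitySeq | str],
    downstream: Sequence[VicinitySeq | str],
    k: int,
) -> PatternCensus:
    """Census of {R,Y}^k patterns over the two subsets, zero counts included.

    Inputs may be raw A/C/G/U sequences (recoded here) or already R/Y-recoded
    strings.  The pooled total percentage is computed from pooled counts:
    (count_up + count_down) / (n_up + n_down) * 100.
    """
    def census(seqs: list[str]) -> dict[str, int]:
        counts = {"".join(p): 0 for p in product("RY", repeat=k)}
        for s in seqs:
            if len(s) != k:
                raise ValueError(f"sequence {s!r} does not have length {k}")
            ry = s if set(s) <= {"R", "Y"} else recode_ry(s)
            counts[ry] += 1
        return counts

    up = census(_as_strings(upstream))
    down = census(_as_strings(downstream))
    n_up, n_down = sum(up.values()), sum(down.values())
    patterns = sorted(up)
    rows = []
    for pat in patterns:
        cu, cd = up[pat], down[pat]
        rows.append({
            "pattern": pat,
            "count_up": cu,
            "count_down": cd,
            "pct_up": cu / n_up * 100.0 if n_up else 0.0,
            "pct_down": cd / n_down * 100.0 if n_down else 0.0,
            "pct_total": (cu + cd) / (n_up + n_down) * 100.0 if n_up + n_down else 0.0,
        })
    return PatternCensus(k, pd.DataFrame(rows))
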