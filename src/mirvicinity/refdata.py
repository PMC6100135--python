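"""Bundled reference data for the Viridiplantae pre-miRNA vicinity analysis.

These small tables summarize a miRBase-scale screen of plant precursor
hairpins: the per-cell counts of symmetric 1-1 and 2-2 internal loops found
near the miRNA:miRNA* duplex in 5975 predicted secondary structures, and the
RMSD/eRMSD values of 19 duplex-vicinity 3D fragments aligned to a reference
within each of the four phyla.  They serve as fixed inputs for the summary
recomputations (percentages, averages, maxima) — the underlying miRBase
snapshot and structure predictions are not part of this package.
"""

from __future__ import annotations

#: structures analyzed in the secondary-structure screen (the S4 set)
TOTAL_STRUCTURES = 5975

#: (motif label, distance D) -> (motif count, structures with at least one)
MOTIF_CELLS: dict[tuple[str, int], tuple[int, int]] = {
    ("1-1", 1): (1397, 1288),
    ("1-1", 2): (861, 826),
    ("1-1", 3): (1043, 989),
    ("1-1", 4): (807, 769),
    ("2-2", 1): (190, 187),
    ("2-2", 2): (149, 147),
    ("2-2", 3): (221, 219),
    ("2-2", 4): (118, 117),
}

PHYLA = ("Chlorophyta", "Coniferophyta", "Embryophyta", "Magnoliophyta")

#: per-phylum RMSD of fragments 1..19 against the reference fragment [A]
RMSD_VALUES: dict[str, tuple[float, ...]] = {
    "Chlorophyta": (2.112, 0.278, 0.256, 0.117, 0.467, 2.209, 0.257, 0.560,
                    0.142, 0.864, 0.502, 0.547, 0.034, 0.389, 1.155, 0.139,
                    0.686, 0.637, 2.159),
    "Coniferophyta": (0.463, 0.430, 1.194, 0.381, 0.258, 1.228, 0.469, 1.226,
                      1.018, 0.412, 0.461, 0.444, 1.377, 0.846, 1.036, 0.481,
                      1.210, 0.390, 0.266),
    "Embryophyta": (1.882, 0.290, 2.058, 1.626, 2.351, 1.810, 1.966, 1.587,
                    1.773, 1.247, 0.910, 1.573, 0.974, 1.546, 0.944, 0.837,
                    1.839, 1.730, 0.330),
    "Magnoliophyta": (2.245, 2.270, 1.135, 0.679, 0.352, 0.567, 0.123, 0.449,
                      2.171, 1.672, 0.845, 0.607, 1.171, 0.963, 0.836, 1.094,
                      0.597, 1.344, 2.304),
}

#: per-phylum eRMSD of fragments 1..19 against the reference fragment [A]
ERMSD_VALUES: dict[str, tuple[float, ...]] = {
    "Chlorophyta": (0.459, 0.788, 0.587, 0.291, 0.477, 0.432, 0.561, 0.442,
                    0.459, 0.438, 0.386, 0.251, 0.605, 0.410, 0.410, 0.463,
                    0.564, 0.528, 0.453),
    "Coniferophyta": (0.765, 0.771, 0.436, 1.047, 1.047, 0.746, 1.025, 0.799,
                      0.675, 0.800, 0.749, 0.753, 0.745, 0.680, 0.891, 0.729,
                      1.023, 1.058, 0.712),
    "Embryophyta": (0.802, 0.434, 0.725, 0.776, 0.868, 0.858, 0.868, 0.817,
                    0.767, 0.842, 1.080, 0.841, 0.906, 0.791, 0.883, 0.901,
                    0.788, 0.764, 0.810),
    "Magnoliophyta": (0.554, 0.503, 0.730, 1.101, 0.325, 0.444, 0.832, 0.365,
                      0.455, 0.643, 0.390, 0.398, 0.457, 0.447, 0.394, 0.467,
                      0.331, 0.604, 0.604),
}
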