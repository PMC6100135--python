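import itertools

import pytest

import mirvicinity as mv
from mirvicinity.motif_seeker import summary_from_cell_counts
from mirvicinity.seq_patterns import round_half_up


def locus(start, end, arm="five_prime"):
    return mv.MiRNALocus(start, end, arm, "experimental")


class TestFindMotifs:
    def test_symmetric_loop_at_distance_one(self):
        """Hand-enumerated 30-nt hairpin: 1-1 loop at positions 4/27."""
        pt = mv.parse_dotbracket("(((.((((((((......)))))))).)))")
        motifs = mv.find_motifs(pt, locus(5, 12), 4)
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.kind, m.size5, m.size3) == ("internal_loop", 1, 1)
        assert m.symmetric and m.side == "upstream" and m.distance == 1
        assert m.positions5 == (4,) and m.positions3 == (27,)

    def test_fully_paired_vicinity_has_no_motifs(self):
        """Perfect stem: upstream fully paired, downstream walk crosses the
        terminal loop, which is excluded."""
        pt = mv.parse_dotbracket("((((((....))))))")
        assert mv.find_motifs(pt, locus(3, 6), 2) == []

    def test_bulge_on_walked_strand(self):
        pt = mv.parse_dotbracket("((.((((....))))))")
        motifs = mv.find_motifs(pt, locus(4, 7), 4)
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.kind, m.size5, m.size3, m.side, m.distance) == ("bulge", 1, 0, "upstream", 1)
        assert m.positions5 == (3,) and m.positions3 == ()

    def test_motif_beyond_window_not_reported(self):
        # loop at distance 3; window 2 must miss it, window 3 must find it
        spec = mv.PrecursorSpec(planted=(mv.PlantedMotif("internal_loop", 1, 1, "upstream", 3),),
                                seed=0)
        rec, pt, truth = mv.simulate_precursor(spec)
        assert mv.find_motifs(pt, rec.loci[0], 2) == []
        assert mv.find_motifs(pt, rec.loci[0], 3) == truth

    def test_hairpin_loop_never_reported_at_any_window(self):
        rec, pt, _ = mv.simulate_precursor(mv.PrecursorSpec(terminal_loop_len=4, seed=0))
        for window in (1, 2, 3, 4):
            assert mv.find_motifs(pt, rec.loci[0], window) == []

    def test_junction_aborts_walk(self, caplog):
        # two hairpins sharing a multiloop right upstream of the locus
        db = "((..((((....))))..((((....))))..))"
        pt = mv.parse_dotbracket(db)
        with caplog.at_level("INFO", logger="mirvicinity.motif_seeker"):
            motifs = mv.find_motifs(pt, locus(19, 22), 4)
        assert motifs == []
        assert any("junction" in rec.message for rec in caplog.records)

    def test_errors(self):
        pt = mv.parse_dotbracket("((((....))))")
        with pytest.raises(ValueError, match="window"):
            mv.find_motifs(pt, locus(3, 4), 0)
        with pytest.raises(ValueError, match="outside"):
            mv.find_motifs(pt, locus(3, 99), 4)

    def test_deterministic_and_ordered(self):
        spec = mv.PrecursorSpec(
            duplex_len=12,
            planted=(mv.PlantedMotif("internal_loop", 1, 1, "downstream", 2),
                     mv.PlantedMotif("bulge", 1, 0, "upstream", 1),
                     mv.PlantedMotif("internal_loop", 2, 2, "upstream", 3)),
            seed=4)
        rec, pt, _ = mv.simulate_precursor(spec)
        out1 = mv.find_motifs(pt, rec.loci[0], 4)
        out2 = mv.find_motifs(pt, rec.loci[0], 4)
        assert out1 == out2
        keys = [(m.side, m.distance) for m in out1]
        order = {"upstream": 0, "downstream": 1}
        assert keys == sorted(keys, key=lambda k: (order[k[0]], k[1]))


class TestStrandRelabelInvariance:
    @pytest.mark.parametrize("seed", range(10))
    def test_dedup_makes_result_locus_order_independent(self, seed):
        spec = mv.PrecursorSpec(
            duplex_len=14, terminal_loop_len=7, basal_stem_len=5,
            planted=(mv.PlantedMotif("internal_loop", 1, 1, "upstream", seed % 4 + 1),
                     mv.PlantedMotif("internal_loop", 2, 2, "downstream",
                                     (seed + 2) % 4 + 1)),
            seed=seed)
        rec, pt, truth = mv.simulate_precursor(spec)
        fwd = mv.find_motifs_all_loci(pt, rec.loci, 4)
        rev = mv.find_motifs_all_loci(pt, list(rec.loci)[::-1], 4)
        assert fwd == rev == truth


class TestSummarizeMotifs:
    @staticmethod
    def _stub(label_sizes, side, distance):
        n, m = label_sizes
        kind = "bulge" if (n == 0) != (m == 0) else "internal_loop"
        p5 = tuple(range(10, 10 + n))
        p3 = tuple(range(50, 50 + m))
        return mv.StructureMotif(kind, n, m, side, distance, p5, p3)

    def test_printed_cell_percentage(self):
        """1288 structures out of 5975 is 21.56%."""
        per_structure = [(f"s{i}", [self._stub((1, 1), "upstream", 1)])
                         for i in range(1288)]
        summary = mv.summarize_motifs(per_structure, 5975)
        assert round_half_up(summary.percent("1-1", 1), 2) == 21.56

    def test_two_motifs_one_structure(self):
        motifs = [self._stub((1, 1), "upstream", 1), self._stub((1, 1), "downstream", 1)]
        summary = mv.summarize_motifs([("s1", motifs)], 10)
        cell = summary.cell("1-1", 1)
        assert cell.motif_count == 2 and cell.structures_with_motif == 1

    def test_empty_input_all_zero(self):
        summary = mv.summarize_motifs([], 0)
        assert summary.table.empty and summary.total_structures == 0

    def test_structures_never_exceed_motifs(self):
        rng_specs = [
            mv.PrecursorSpec(
                duplex_len=10,
                planted=(mv.PlantedMotif("internal_loop", 1, 1, "upstream", 1 + i % 4),),
                seed=i, record_id=f"r{i}")
            for i in range(12)
        ]
        per_structure = []
        for spec in rng_specs:
            rec, pt, _ = mv.simulate_precursor(spec)
            per_structure.append((rec.id, mv.find_motifs(pt, rec.loci[0], 4)))
        summary = mv.summarize_motifs(per_structure, len(per_structure))
        assert (summary.table.structures_with_motif <= summary.table.motif_count).all()


class TestCombinedPercent:
    def test_additive_convention_on_printed_counts(self):
        summary = summary_from_cell_counts(
            {("1-1", 1): (1397, 1288), ("1-1", 2): (861, 826), ("1-1", 3): (1043, 989)},
            5975)
        assert round_half_up(mv.combined_percent(summary, "1-1", [1, 2, 3]), 2) == 51.93

    def test_single_distance_equals_cell(self):
        summary = summary_from_cell_counts({("2-2", 1): (10, 9)}, 100)
        assert mv.combined_percent(summary, "2-2", [1]) == summary.percent("2-2", 1)

    def test_two_structures_two_distances_sum_to_100(self):
        per_structure = []
        for sid, d in (("a", 1), ("b", 2)):
            spec = mv.PrecursorSpec(
                planted=(mv.PlantedMotif("internal_loop", 1, 1, "upstream", d),),
                seed=0, record_id=sid)
            rec, pt, _ = mv.simulate_precursor(spec)
            per_structure.append((sid, mv.find_motifs(pt, rec.loci[0], 4)))
        summary = mv.summarize_motifs(per_structure, 2)
        assert mv.combined_percent(summary, "1-1", [1, 2]) == 100.0

    def test_unknown_label_errors(self):
        summary = summary_from_cell_counts({("1-1", 1): (1, 1)}, 10)
        with pytest.raises(KeyError):
            mv.combined_percent(summary, "9-9", [1])


class TestPlantedRecoveryProperty:
    def test_exact_recovery_over_seeded_sweep(self):
        """Precision and recall 1.0 across kinds, sizes, sides, distances."""
        kinds = [("internal_loop", 1, 1), ("internal_loop", 2, 2),
                 ("bulge", 1, 0), ("bulge", 2, 0)]
        n_cases = 0
        for (kind, n, m), side, dist, seed in itertools.product(
                kinds, ("upstream", "downstream"), (1, 2, 3, 4), range(7)):
            spec = mv.PrecursorSpec(
                duplex_len=10, terminal_loop_len=6, basal_stem_len=4,
                planted=(mv.PlantedMotif(kind, n, m, side, dist),), seed=seed)
            rec, pt, truth = mv.simulate_precursor(spec)
            assert mv.find_motifs(pt, rec.loci[0], 4) == truth
            n_cases += 1
        assert n_cases >= 200
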