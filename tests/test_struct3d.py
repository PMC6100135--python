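import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

import mirvicinity as mv
from conftest import ermsd_direct_summation, rmsd_rotation_search


def helix_fragment(n=8, seed=0):
    return mv.simulate_fragment_set(1, mv.FragmentSpec(n_residues=n, seed=seed))[0]


def rigid_copy(frag, seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    trans = rng.uniform(-8, 8, 3)
    residues = [
        mv.Residue3D(r.number, r.base, {k: rot @ np.asarray(v) + trans
                                        for k, v in r.atoms.items()})
        for r in frag.residues
    ]
    return mv.Fragment3D(tuple(residues), frag.atom_subset)


class TestKabsch:
    def test_identity_gives_zero(self):
        frag = helix_fragment()
        assert mv.kabsch_superpose(frag, frag).rmsd < 1e-12

    def test_rigid_motion_invariance(self):
        a = helix_fragment()
        coords = a.coords()
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([5.0, 5.0, 5.0])
        result = mv.kabsch_superpose(moved, coords)
        assert result.rmsd < 1e-9
        assert np.isclose(np.linalg.det(result.rotation), 1.0)

    def test_matches_rotation_search_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(10, 3)) * 4
        q = p + rng.normal(scale=0.5, size=p.shape)
        ours = mv.kabsch_superpose(p, q).rmsd
        oracle = rmsd_rotation_search(p, q, seed=1)
        assert abs(ours - oracle) < 2e-3
        assert ours <= oracle + 1e-9  # least-squares optimum is a lower bound

    def test_symmetry_and_pretransform_invariance(self):
        a, b = mv.simulate_fragment_pair(mv.FragmentSpec(noise_sigma=0.4, seed=3))
        r_ab = mv.kabsch_superpose(a, b).rmsd
        r_ba = mv.kabsch_superpose(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        moved = rigid_copy(a, seed=9)
        assert mv.kabsch_superpose(moved, b).rmsd == pytest.approx(r_ab, abs=1e-9)

    def test_reflection_excluded(self):
        # a mirror image must NOT superpose to zero with a proper rotation
        frag = helix_fragment()
        coords = frag.coords()
        mirrored = coords * np.array([1.0, 1.0, -1.0])
        result = mv.kabsch_superpose(mirrored, coords)
        assert result.rmsd > 0.1
        assert np.isclose(np.linalg.det(result.rotation), 1.0)

    def test_degenerate_geometry(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            mv.kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            mv.kabsch_superpose(line[:2], line[:2])


class TestERMSD:
    def test_identical_and_rigid_copies_give_zero(self):
        frag = helix_fragment()
        assert mv.ermsd(frag, frag).ermsd < 1e-12
        assert mv.ermsd(frag, rigid_copy(frag, 5)).ermsd < 1e-9

    def test_beyond_cutoff_everywhere_gives_zero(self):
        # two residues 100 A apart: scaled distance >> cutoff in both inputs
        def far_pair(offset):
            res = []
            for i, shift in enumerate(([0, 0, 0], [100 + offset, 0, 0])):
                atoms = {"C2": np.array([1.0, 0, 0]) + shift,
                         "C4": np.array([0, 1.0, 0]) + shift,
                         "C6": np.array([0, 0, 1.0]) + shift}
                res.append(mv.Residue3D(i + 1, "A", atoms))
            return mv.Fragment3D(tuple(res), ("C2", "C4", "C6"))
        assert mv.ermsd(far_pair(0.0), far_pair(30.0)).ermsd == 0.0

    def test_single_base_rotation_detected_and_matches_oracle(self):
        frag = helix_fragment()
        residues = list(frag.residues)
        target = residues[3]
        origin = (np.asarray(target.atoms["C2"]) + target.atoms["C4"] + target.atoms["C6"]) / 3
        x = np.asarray(target.atoms["C2"], float) - origin
        y0 = np.asarray(target.atoms["C4"], float) - origin
        normal = np.cross(x, y0)
        normal /= np.linalg.norm(normal)
        rot = Rotation.from_rotvec(np.deg2rad(30) * normal).as_matrix()
        atoms = {k: rot @ (np.asarray(v) - origin) + origin for k, v in target.atoms.items()}
        residues[3] = mv.Residue3D(target.number, target.base, atoms)
        twisted = mv.Fragment3D(tuple(residues), frag.atom_subset)
        result = mv.ermsd(frag, twisted)
        assert result.ermsd > 0
        assert result.ermsd == pytest.approx(ermsd_direct_summation(frag, twisted), abs=1e-9)

    def test_symmetry_and_rigid_invariance(self):
        a, b = mv.simulate_fragment_pair(mv.FragmentSpec(noise_sigma=0.3, seed=7))
        assert mv.ermsd(a, b).ermsd == pytest.approx(mv.ermsd(b, a).ermsd, abs=1e-12)
        assert mv.ermsd(rigid_copy(a, 2), b).ermsd == pytest.approx(
            mv.ermsd(a, b).ermsd, abs=1e-9)

    def test_oracle_agreement_on_seeded_instances(self):
        for seed in range(5):
            a, b = mv.simulate_fragment_pair(mv.FragmentSpec(noise_sigma=0.6, seed=seed))
            assert mv.ermsd(a, b).ermsd == pytest.approx(
                ermsd_direct_summation(a, b), abs=1e-9)

    def test_residue_count_mismatch(self):
        a = helix_fragment(8)
        b = helix_fragment(6)
        with pytest.raises(ValueError, match="mismatch"):
            mv.ermsd(a, b)


class TestExtractDuplexFragments:
    @staticmethod
    def model(n=40):
        return mv.simulate_fragment_set(1, mv.FragmentSpec(n_residues=n, seed=0))[0]

    def test_default_ranges(self):
        model = self.model()
        locus = mv.MiRNALocus(10, 30)
        five, three = mv.extract_duplex_fragments(model, locus)
        assert [r.number for r in five.residues] == list(range(6, 14))
        assert [r.number for r in three.residues] == list(range(27, 35))

    def test_purely_external(self):
        five, three = mv.extract_duplex_fragments(self.model(), mv.MiRNALocus(10, 30),
                                                  in_nt=0, out_nt=4)
        assert [r.number for r in five.residues] == [6, 7, 8, 9]
        assert [r.number for r in three.residues] == [31, 32, 33, 34]

    def test_insufficient_residues_names_side(self):
        with pytest.raises(ValueError, match="5'-side"):
            mv.extract_duplex_fragments(self.model(), mv.MiRNALocus(3, 30))


class TestAlignSet:
    def test_twenty_fragments_give_nineteen_results(self):
        frags = mv.simulate_fragment_set(20, mv.FragmentSpec(seed=4))
        results = mv.align_set(frags, 0)
        assert len(results) == 19
        assert len(mv.ermsd_set(frags, 0)) == 19

    def test_identical_pair(self):
        frag = helix_fragment()
        (result,) = mv.align_set([frag, frag], 0)
        assert result.rmsd < 1e-12

    def test_reference_excluded(self):
        frags = mv.simulate_fragment_set(5, mv.FragmentSpec(noise_sigma=0.5, seed=8))
        results = mv.align_set(frags, 2)
        assert len(results) == 4
        # the self-comparison (rmsd exactly 0) is not among the outputs
        assert all(r.rmsd > 0 for r in results)

    def test_bad_reference_index(self):
        frags = mv.simulate_fragment_set(3, mv.FragmentSpec(seed=1))
        with pytest.raises(ValueError, match="reference index"):
            mv.align_set(frags, 5)


class TestSummarizeDistances:
    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mv.summarize_distances({"g": []})

    def test_mean_and_max(self):
        df = mv.summarize_distances({"g": [0.1, 0.2, 0.6]}).set_index("group")
        assert df.loc["g", "mean"] == 0.3 and df.loc["g", "max"] == 0.6


class TestNoiseBehaviour:
    def test_rmsd_monotone_in_noise(self):
        """Expected RMSD grows with coordinate noise sigma."""
        sigmas = [0.05, 0.2, 0.4, 0.6, 0.8, 1.0]
        means = []
        for s_idx, sigma in enumerate(sigmas):
            vals = []
            for rep in range(50):
                a, b = mv.simulate_fragment_pair(
                    mv.FragmentSpec(noise_sigma=sigma, seed=1000 * s_idx + rep))
                vals.append(mv.kabsch_superpose(b, a).rmsd)
            means.append(np.mean(vals))
        rho, _ = spearmanr(sigmas, means)
        assert rho > 0.95

    def test_mean_rmsd_matches_gaussian_expectation(self):
        """Per-coordinate noise sigma on N atoms leaves ~(3N-6) residual
        degrees of freedom after the rigid fit: rmsd ~ sigma*sqrt((3N-6)/N)."""
        sigma, n_res = 0.5, 8
        n_atoms = n_res * len(mv.synthetic_data.FRAGMENT_ATOMS)
        expected = sigma * np.sqrt((3 * n_atoms - 6) / n_atoms)
        vals = []
        for seed in range(100):
            a, b = mv.simulate_fragment_pair(
                mv.FragmentSpec(n_residues=n_res, noise_sigma=sigma, seed=seed))
            vals.append(mv.kabsch_superpose(b, a).rmsd)
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)
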