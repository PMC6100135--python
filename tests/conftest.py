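import numpy as np
import pytest

import mirvicinity as mv


@pytest.fixture
def worked_example():
    """30-nt hairpin with a single 1-1 internal loop at distance 1 upstream."""
    spec = mv.PrecursorSpec(
        duplex_len=8, terminal_loop_len=6, basal_stem_len=3,
        planted=(mv.PlantedMotif("internal_loop", 1, 1, "upstream", 1),),
        seed=7,
    )
    return mv.simulate_precursor(spec)


@pytest.fixture
def toy_records():
    """Three precursors with flank profiles (8,8), (4,7), (3,10)."""
    def make(rid: str, up: int, down: int, mirna_len: int = 5):
        seq = "A" * up + "G" * mirna_len + "U" * down
        locus = mv.MiRNALocus(up + 1, up + mirna_len, "five_prime", "experimental")
        return mv.PrecursorRecord(rid, seq, (locus,), "toy", "Toyphyta")
    return [make("A", 8, 8), make("B", 4, 7), make("C", 3, 10)]


def rmsd_rotation_search(p: np.ndarray, q: np.ndarray, n_starts: int = 12,
                         seed: int = 0) -> float:
    """Brute-force RMSD oracle: numerical search over rotations.

    Independent of the SVD-based implementation: centers both clouds and
    minimizes the residual over rotation vectors from many random starts.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((p0 @ r.T - q0) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(objective, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best


def ermsd_direct_summation(fa, fb) -> float:
    """Direct (loop-based) evaluation of the eRMSD formula."""
    scale = np.array([5.0, 5.0, 3.0])
    cutoff = 2.4
    gamma = np.pi / cutoff

    def frames(frag):
        out = []
        for res in frag.residues:
            c2, c4, c6 = (np.asarray(res.atoms[n], float) for n in ("C2", "C4", "C6"))
            o = (c2 + c4 + c6) / 3.0
            x = (c2 - o) / np.linalg.norm(c2 - o)
            y = c4 - o
            y = y - x * (y @ x)
            y = y / np.linalg.norm(y)
            out.append((o, np.stack([x, y, np.cross(x, y)])))
        return out

    fra, frb = frames(fa), frames(fb)
    n = len(fra)
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            def g(fr):
                oj, rj = fr[j]
                ok, _ = fr[k]
                v = rj @ (ok - oj) / scale
                r = np.linalg.norm(v)
                if r >= cutoff:
                    return np.zeros(4)
                return np.array([*(np.sin(gamma * r) * v / r), 1 + np.cos(gamma * r)]) / gamma
            total += float(np.sum((g(fra) - g(frb)) ** 2))
    return float(np.sqrt(total / n))
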