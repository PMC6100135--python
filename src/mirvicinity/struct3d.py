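"""3D comparison of duplex-overlapping fragments: Kabsch RMSD and eRMSD.

Fragments of the miRNA:miRNA* duplex vicinity (by default 4 nt outside + 4 nt
inside the miRNA on each side) are compared pairwise.  RMSD uses the classic
Kabsch least-squares rigid superposition (reflections excluded).  eRMSD scores
only the relative positions and orientations of nucleobases: each base gets an
orthonormal frame built from its C2/C4/C6 ring atoms, inter-base displacement
vectors are anisotropically scaled (5 A in-plane, 3 A along the base normal),
mapped to a smooth 4-component G-vector that vanishes beyond a cutoff, and the
two structures' G-vectors are compared in the root-mean-square sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Fragment3D, MiRNALocus
from .seq_patterns import round_half_up

# eRMSD method constants: ellipsoidal scaling of the displacement (two
# in-plane axes, base normal) and the scaled-distance cutoff.
ERMSD_SCALE = np.array([5.0, 5.0, 3.0])
ERMSD_CUTOFF = 2.4
ERMSD_GAMMA = np.pi / ERMSD_CUTOFF


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # applied as x @ R.T + t
    n_atoms: int


@dataclass(frozen=True)
class ERMSDResult:
    ermsd: float
    n_residues: int


def _check_geometry(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError(f"need at least 3 atoms for superposition, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: atoms are collinear")


def kabsch_superpose(mobile: Fragment3D | np.ndarray,
                     reference: Fragment3D | np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Atom correspondence is positional (same residue order, same atom subset).
    Returns the proper rotation R and translation t minimizing
    ``|| mobile @ R.T + t - reference ||`` and the resulting RMSD.
    """
    p = mobile.coords() if isinstance(mobile, Fragment3D) else np.asarray(mobile, float)
    q = reference.coords() if isinstance(reference, Fragment3D) else np.asarray(reference, float)
    if p.shape != q.shape:
        raise ValueError(f"atom count mismatch: {p.shape[0]} vs {q.shape[0]}")
    _check_geometry(p)
    _check_geometry(q)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    moved = p0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q0) ** 2, axis=1))))
    translation = qc - pc @ rot.T
    return SuperpositionResult(rmsd, rot, translation, p.shape[0])


# ---------------------------------------------------------------------------
# eRMSD
# ---------------------------------------------------------------------------

def base_frames(fragment: Fragment3D) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue base frames from C2/C4/C6.

    Returns (origins, rotations): origins (N, 3) are the ring-atom centroids;
    rotations (N, 3, 3) have the frame axes as rows, so ``rotations[i] @ v``
    expresses a lab-frame vector v in residue i's base frame.
    """
    origins = []
    axes = []
    for res in fragment.residues:
        try:
            c2 = np.asarray(res.atoms["C2"], float)
            c4 = np.asarray(res.atoms["C4"], float)
            c6 = np.asarray(res.atoms["C6"], float)
        except KeyError as exc:
            raise ValueError(f"residue {res.number} is missing base-frame atom {exc}") from exc
        origin = (c2 + c4 + c6) / 3.0
        x = c2 - origin
        nx = np.linalg.norm(x)
        if nx < 1e-9:
            raise ValueError(f"residue {res.number}: degenerate base geometry")
        x = x / nx
        y = c4 - origin
        y = y - x * (y @ x)
        ny = np.linalg.norm(y)
        if ny < 1e-9:
            raise ValueError(f"residue {res.number}: collinear base-frame atoms")
        y = y / ny
        z = np.cross(x, y)
        origins.append(origin)
        axes.append(np.stack([x, y, z]))
    return np.array(origins), np.array(axes)


def gvectors(fragment: Fragment3D) -> np.ndarray:
    """(N, N, 4) array of G-vectors over ordered residue pairs (j, k), j != k.

    The displacement from base j's origin to base k's, expressed in base j's
    frame and scaled by the ellipsoid axes, gives the scaled vector r with
    norm r.  For r < cutoff,

        G = ( sin(g r) x/r, sin(g r) y/r, sin(g r) z/r, 1 + cos(g r) ) / g

    with g = pi / cutoff; beyond the cutoff G = 0.  Diagonal entries are 0.
    """
    origins, axes = base_frames(fragment)
    n = len(origins)
    disp = origins[None, :, :] - origins[:, None, :]            # (j, k, 3) lab frame
    local = np.einsum("jab,jkb->jka", axes, disp)               # in frame of j
    scaled = local / ERMSD_SCALE
    r = np.linalg.norm(scaled, axis=-1)                         # (j, k)
    g = np.zeros((n, n, 4))
    mask = (r > 0) & (r < ERMSD_CUTOFF)
    rm = r[mask]
    g[mask, :3] = np.sin(ERMSD_GAMMA * rm)[:, None] * scaled[mask] / rm[:, None]
    g[mask, 3] = 1.0 + np.cos(ERMSD_GAMMA * rm)
    return g / ERMSD_GAMMA


def ermsd(a: Fragment3D, b: Fragment3D) -> ERMSDResult:
    """eRMSD between two position-matched fragments.

    sqrt( (1/N) * sum over ordered pairs |G_a - G_b|^2 ), N = residue count.
    Zero for rigid-motion copies; also zero when every inter-base scaled
    distance exceeds the cutoff in both structures.
    """
    if a.n_residues != b.n_residues:
        raise ValueError(f"residue count mismatch: {a.n_residues} vs {b.n_residues}")
    ga, gb = gvectors(a), gvectors(b)
    value = float(np.sqrt(np.sum((ga - gb) ** 2) / a.n_residues))
    return ERMSDResult(value, a.n_residues)


# ---------------------------------------------------------------------------
# Fragment extraction and set-level comparison
# ---------------------------------------------------------------------------

def extract_duplex_fragments(
    model: Fragment3D,
    locus: MiRNALocus,
    in_nt: int = 4,
    out_nt: int = 4,
) -> tuple[Fragment3D, Fragment3D]:
    """Cut the two duplex-overlapping fragments around a miRNA locus.

    The 5'-side fragment spans residues start-out_nt .. start+in_nt-1, the
    3'-side fragment end-in_nt+1 .. end+out_nt (residue numbers, inclusive):
    ``out_nt`` residues outside and ``in_nt`` residues inside the miRNA each.
    """
    by_number = {res.number: res for res in model.residues}

    def cut(lo: int, hi: int, side: str) -> Fragment3D:
        missing = [num for num in range(lo, hi + 1) if num not in by_number]
        if missing:
            raise ValueError(
                f"{side} fragment needs residues {lo}..{hi}; missing {missing}"
            )
        residues = tuple(by_number[num] for num in range(lo, hi + 1))
        return Fragment3D(residues, model.atom_subset)

    five = cut(locus.start - out_nt, locus.start + in_nt - 1, "5'-side")
    three = cut(locus.end - in_nt + 1, locus.end + out_nt, "3'-side")
    return five, three


def align_set(
    fragments: Sequence[Fragment3D],
    reference_index: int,
) -> list[SuperpositionResult]:
    """Superpose every fragment onto the chosen reference.

    One result per non-reference fragment, in input order (19 results for a
    set of 20).  The reference compared with itself is excluded.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to align")
    if not (0 <= reference_index < len(fragments)):
        raise ValueError(f"reference index {reference_index} out of range 0..{len(fragments) - 1}")
    ref = fragments[reference_index]
    return [kabsch_superpose(frag, ref)
            for i, frag in enumerate(fragments) if i != reference_index]


def ermsd_set(fragments: Sequence[Fragment3D], reference_index: int) -> list[ERMSDResult]:
    """eRMSD of every non-reference fragment against the chosen reference."""
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to compare")
    if not (0 <= reference_index < len(fragments)):
        raise ValueError(f"reference index {reference_index} out of range 0..{len(fragments) - 1}")
    ref = fragments[reference_index]
    return [ermsd(frag, ref) for i, frag in enumerate(fragments) if i != reference_index]


def summarize_distances(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Arithmetic mean and maximum per group, rounded to 3 decimals (half-up)."""
    rows = []
    for name, values in groups.items():
        values = list(values)
        if not values:
            raise ValueError(f"group {name!r} is empty")
        rows.append({
            "group": name,
            "n": len(values),
            "mean": round_half_up(float(np.mean(values)), 3),
            "max": round_half_up(float(np.max(values)), 3),
        })
    return pd.DataFrame(rows, columns=["group", "n", "mean", "max"])
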