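"""Least-squares Calpha superposition and RMSD summaries.

Rigid-body alignment uses the Kabsch solution (SVD of the covariance of the
centred point sets, with the determinant guard against improper rotations).
The cross-structure RMSD matrix mirrors how overall conformational drift is
summarised across a wild-type/mutant series, and the residue-wise RMSD
profiles localise where an aligned ensemble actually differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Structure, map_residues

__all__ = ["SuperpositionResult", "kabsch", "rmsd_matrix", "residuewise_rmsd",
           "structure_rmsd"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping the moving set onto the reference:
    ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom over the matched pairs
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(ref_coords: np.ndarray, mov_coords: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mov_coords`` onto ``ref_coords``.

    Both arrays must be (n, 3) with n >= 3 and not collinear.  The returned
    RMSD is the global minimum over all rotations and translations.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if min(np.linalg.matrix_rank(ref_c, tol=1e-8),
           np.linalg.matrix_rank(mov_c, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation is not unique")

    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])  # reflection guard
    rotation = vt.T @ flip @ u.T
    translation = ref.mean(axis=0) - rotation @ mov.mean(axis=0)
    moved = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_matched=n)


def _matched_coords(ref: Structure, other: Structure) -> tuple[np.ndarray, np.ndarray]:
    mapping = map_residues(ref, other)
    ref_idx = np.array([i for i, _ in mapping.pairs]) - 1
    oth_idx = np.array([j for _, j in mapping.pairs]) - 1
    return ref.coords[ref_idx], other.coords[oth_idx]


def structure_rmsd(ref: Structure, other: Structure) -> SuperpositionResult:
    """Kabsch superposition over the residues matched by author number."""
    a, b = _matched_coords(ref, other)
    return kabsch(a, b)


def rmsd_matrix(structures: list[Structure]) -> pd.DataFrame:
    """Symmetric all-against-all Calpha RMSD table (Angstrom).

    Each cell is the Kabsch RMSD over the pair's matched residues; the
    diagonal is zero by construction.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    ids = [s.id for s in structures]
    m = np.zeros((len(structures), len(structures)))
    for a in range(len(structures)):
        for b in range(a + 1, len(structures)):
            try:
                r = structure_rmsd(structures[a], structures[b]).rmsd
            except ValueError as exc:
                raise ValueError(f"superposition failed for pair ({ids[a]}, {ids[b]}): {exc}")
            m[a, b] = m[b, a] = r
    return pd.DataFrame(m, index=ids, columns=ids)


def residuewise_rmsd(structures: list[Structure], reference: Structure) -> pd.Series:
    """Per-residue positional spread across an aligned ensemble.

    Every structure is superposed onto ``reference`` over the residues all
    structures share; for each such residue the root-mean-square deviation of
    its Calpha around the ensemble-mean position is reported, indexed by
    author residue number.
    """
    if not structures:
        raise ValueError("need at least one structure")
    common = set(reference.author_numbers)
    for s in structures:
        common &= set(s.author_numbers)
    numbers = sorted(common)
    if not numbers:
        raise ValueError("no residues shared by all structures")

    ref_pos = {r.author_number: r.ca for r in reference.residues}
    ref_sel = np.array([ref_pos[n] for n in numbers])
    stack = []
    for s in structures:
        pos = {r.author_number: r.ca for r in s.residues}
        sel = np.array([pos[n] for n in numbers])
        stack.append(kabsch(ref_sel, sel).apply(sel))
    arr = np.stack(stack)  # (n_struct, n_res, 3)
    mean = arr.mean(axis=0)
    dev = np.sqrt(np.mean(np.sum((arr - mean) ** 2, axis=2), axis=0))
    return pd.Series(dev, index=pd.Index(numbers, name="residue"), name="rmsd")
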