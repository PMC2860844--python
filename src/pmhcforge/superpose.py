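"""Rigid-body superposition (Kabsch) and the RMSD conventions used for validation.

Two validation conventions are exposed for comparing a modelled complex with a
reference: fit the peptides by C-alpha and report all-heavy-atom peptide RMSD
(:func:`fit_by_peptide_ca`), or fit the receptors by C-alpha and report the
peptide RMSD *without* refitting the peptide (:func:`fit_by_mhc_ca`).  The
second convention also measures placement error inside the cleft and is the
default validation metric; reconstructions under 2.2 angstrom by this metric
are conventionally considered valid reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SuperpositionError
from .structio import PMHCComplex, Structure

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "rmsd_between",
    "apply_transform",
    "fit_by_mhc_ca",
    "fit_by_peptide_ca",
    "VALID_REPRODUCTION_RMSD",
]

#: Conventional upper bound (angstrom) for a docking reproduction to count as valid.
VALID_REPRODUCTION_RMSD = 2.2


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation mapping one point set onto another."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, angstrom
    rmsd: float  # residual over the fitted selection, angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def rmsd_between(A: np.ndarray, B: np.ndarray) -> float:
    """Root mean square deviation between paired coordinates, no fitting."""
    A = np.asarray(A, float).reshape(-1, 3)
    B = np.asarray(B, float).reshape(-1, 3)
    if A.shape != B.shape:
        raise SuperpositionError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.size == 0:
        raise SuperpositionError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of Q onto P (SVD Kabsch).

    Returns the proper rotation R and translation t minimizing
    ``|| (Q R^T + t) - P ||`` and the residual RMSD.  Reflections are
    corrected so det(R) = +1.
    """
    P = np.asarray(P, float).reshape(-1, 3)
    Q = np.asarray(Q, float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise SuperpositionError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points, got {n}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise SuperpositionError("non-finite coordinates")

    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    # collinear sets leave the rotation about the line undetermined
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point set")

    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    moved = Q @ R.T + t
    return SuperpositionResult(R, t, rmsd_between(P, moved))


def apply_transform(obj, result: SuperpositionResult):
    """Return a copy of a Structure or PMHCComplex with the rigid motion applied."""
    if isinstance(obj, PMHCComplex):
        out = obj.copy()
        for sub in (out.mhc, out.peptide):
            sub.set_coords(result.apply(sub.coords()))
        return out
    if isinstance(obj, Structure):
        out = obj.copy()
        out.set_coords(result.apply(out.coords()))
        return out
    raise TypeError(f"cannot transform {type(obj).__name__}")


def _matched_ca(model: PMHCComplex, reference: PMHCComplex) -> tuple[np.ndarray, np.ndarray]:
    ca_m = model.mhc_ca()
    ca_r = reference.mhc_ca()
    common = [k for k in ca_r if k in ca_m]
    if len(common) < 3:
        raise SuperpositionError(
            f"MHC alpha chains share only {len(common)} C-alpha positions; cannot align"
        )
    return (np.array([ca_m[k] for k in common]), np.array([ca_r[k] for k in common]))


def _matched_peptide_heavy(model: PMHCComplex, reference: PMHCComplex) -> tuple[np.ndarray, np.ndarray]:
    rm, rr = model.peptide_residues, reference.peptide_residues
    if len(rm) != len(rr):
        raise SuperpositionError("peptides differ in length")
    A, B = [], []
    for res_m, res_r in zip(rm, rr):
        names_r = [a.name for a in res_r.atoms]
        for name in names_r:
            am = res_m.get(name)
            if am is not None:
                A.append(am.pos)
                B.append(res_r.get(name).pos)
    if not A:
        raise SuperpositionError("no shared peptide atoms")
    return np.array(A), np.array(B)


def fit_by_mhc_ca(model: PMHCComplex, reference: PMHCComplex) -> tuple[PMHCComplex, float]:
    """Superpose by receptor C-alpha atoms; report unfitted peptide heavy-atom RMSD.

    The whole model complex is moved by the transform that best fits its MHC
    alpha-chain C-alpha atoms onto the reference's (matched by residue
    number); the peptide RMSD is then measured in place, so it includes both
    conformational and positional error inside the cleft.
    """
    ca_m, ca_r = _matched_ca(model, reference)
    fit = kabsch(ca_r, ca_m)
    moved = apply_transform(model, fit)
    A, B = _matched_peptide_heavy(moved, reference)
    return moved, rmsd_between(A, B)


def fit_by_peptide_ca(model: PMHCComplex, reference: PMHCComplex) -> float:
    """Superpose the peptides by C-alpha, then report all-heavy-atom peptide RMSD."""
    rm, rr = model.peptide_residues, reference.peptide_residues
    if len(rm) != len(rr):
        raise SuperpositionError("peptides differ in length")
    ca_m = np.array([r.get("CA").pos for r in rm])
    ca_r = np.array([r.get("CA").pos for r in rr])
    fit = kabsch(ca_r, ca_m)
    moved = apply_transform(model, fit)
    A, B = _matched_peptide_heavy(moved, reference)
    return rmsd_between(A, B)
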