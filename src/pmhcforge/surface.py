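"""Accessible surface area and TCR-face topology/electrostatics comparison.

Per-atom solvent-accessible surface area (ASA) is computed by Shrake-Rupley
sphere-point sampling on a deterministic golden-spiral point set (960 points
by default, probe 1.4 angstrom, Chothia-style radii).  The per-position ASA
vector of the bound peptide -- its *ASA signature* -- is the quantity
compared across complexes in cross-reactivity screening: peptides that
stimulate the same T cells tend to show near-identical signatures, and large
signature deviations flag poor cross-recognition candidates.

For the surface seen by the T-cell receptor, solvent-accessible points with
outward normals facing up from the cleft plane are collected into a
:class:`SurfaceMap` carrying per-point elevation (topology) and Coulomb
potential on coarse formal charges, clipped to +/-10 kT/e for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import PmhcError, ScoringError
from .structio import Atom, BACKBONE_ATOMS, PMHCComplex, Residue, Structure
from .energetics import ScoringParams, assign_charges, _params

__all__ = [
    "VDW_RADII",
    "ASASignature",
    "SurfaceMap",
    "sphere_points",
    "shrake_rupley",
    "sas_points",
    "asa_signature",
    "residue_asa",
    "compare_signatures",
    "relative_sidechain_asa",
    "surface_potential",
    "compare_surfaces",
]

#: Chothia-style van der Waals radii (angstrom)
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: thermal energy at 298 K in kcal/mol, for converting potentials to kT/e
KT_KCAL = 0.593

POTENTIAL_CLIP = 10.0


@dataclass
class ASASignature:
    """Per-position whole-residue ASA of a bound peptide, in square angstrom."""

    complex_id: str
    values: np.ndarray  # length n, p1..pn
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < -1e-9):
            raise PmhcError("ASA values must be non-negative")


@dataclass
class SurfaceMap:
    """Sampled TCR-face surface: points, potentials (kT/e, clipped), heights."""

    points: np.ndarray  # (m, 3)
    values: np.ndarray  # potential per point, clipped to +/-POTENTIAL_CLIP
    heights: np.ndarray  # elevation above the cleft reference plane
    plane_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if len(self.points) == 0:
            raise PmhcError("surface map must contain at least one point")
        if np.any(np.abs(self.values) > POTENTIAL_CLIP + 1e-9):
            raise PmhcError("potential values must be clipped to +/-10")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radii(structure: Structure) -> np.ndarray:
    out = []
    for atom in structure.atoms:
        r = VDW_RADII.get(atom.element)
        if r is None:
            raise ScoringError(f"no van der Waals radius for element {atom.element!r}")
        out.append(r)
    return np.array(out)


def _accessible_mask(coords, radii, probe, n_points):
    """Boolean accessibility of each sphere sample point of each atom."""
    unit = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    masks = []
    for i, (c, r) in enumerate(zip(coords, expanded)):
        pts = c + r * unit
        neighbor_idx = [j for j in tree.query_ball_point(c, r + expanded.max())
                        if j != i and np.linalg.norm(coords[j] - c) < r + expanded[j]]
        acc = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            acc &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        masks.append(acc)
    return np.array(masks), unit, expanded


def shrake_rupley(structure: Structure, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in square angstrom."""
    if probe <= 0:
        raise PmhcError("probe radius must be positive")
    if n_points < 100:
        raise PmhcError("need at least 100 sphere points")
    coords = structure.coords()
    radii = _radii(structure)
    masks, _, expanded = _accessible_mask(coords, radii, probe, n_points)
    frac = masks.mean(axis=1)
    return 4.0 * np.pi * expanded**2 * frac


def sas_points(structure: Structure, probe: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_N_POINTS):
    """Accessible surface sample points with outward normals and atom indices."""
    coords = structure.coords()
    radii = _radii(structure)
    masks, unit, expanded = _accessible_mask(coords, radii, probe, n_points)
    pts, normals, owners, weights = [], [], [], []
    for i, acc in enumerate(masks):
        if not acc.any():
            continue
        u = unit[acc]
        pts.append(coords[i] + expanded[i] * u)
        normals.append(u)
        owners.append(np.full(acc.sum(), i))
        # each point represents an equal patch of its atom's expanded sphere
        weights.append(np.full(acc.sum(), 4.0 * np.pi * expanded[i]**2 / n_points))
    if not pts:
        raise PmhcError("structure has no accessible surface")
    return (np.vstack(pts), np.vstack(normals), np.concatenate(owners),
            np.concatenate(weights))


# ---------------------------------------------------------------------------
# ASA signatures


def _complex_structure(complex: PMHCComplex) -> Structure:
    merged = complex.to_structure("asa")
    merged.metadata["capped"] = complex.mhc.metadata.get("capped", False)
    return merged


def residue_asa(structure: Structure, probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> dict[tuple[str, int, str], float]:
    """Whole-residue ASA keyed by (chain, seqnum, icode)."""
    per_atom = shrake_rupley(structure, probe, n_points)
    out = {}
    k = 0
    for cid, residues in structure.chains:
        for res in residues:
            n = len(res.atoms)
            out[(cid, res.seqnum, res.icode)] = float(per_atom[k:k + n].sum())
            k += n
    return out


def asa_signature(complex: PMHCComplex, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> ASASignature:
    """Whole-residue ASA per peptide position, with the MHC occluding."""
    merged = _complex_structure(complex)
    per_atom = shrake_rupley(merged, probe, n_points)
    n_mhc = len(merged.atoms) - len(complex.peptide.atoms)
    values = []
    k = n_mhc
    for res in complex.peptide_residues:
        n = len(res.atoms)
        values.append(float(per_atom[k:k + n].sum()))
        k += n
    return ASASignature(complex.mhc.id, np.array(values), probe, n_points)


def compare_signatures(a: ASASignature, b: ASASignature):
    """Per-position deltas, their RMS, and the position of the largest |delta|."""
    if len(a.values) != len(b.values):
        raise PmhcError(f"signature lengths differ: {len(a.values)} vs {len(b.values)}")
    delta = a.values - b.values
    rms = float(np.sqrt(np.mean(delta**2)))
    worst = int(np.argmax(np.abs(delta))) + 1  # 1-based position
    return delta, rms, worst


def relative_sidechain_asa(complex: PMHCComplex, probe: float = DEFAULT_PROBE,
                           n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Side-chain ASA in complex divided by the free-residue reference.

    The reference is the same residue isolated in vacuum; glycine uses its
    CA atom as the side-chain surrogate.
    """
    merged = _complex_structure(complex)
    per_atom = shrake_rupley(merged, probe, n_points)
    n_mhc = len(merged.atoms) - len(complex.peptide.atoms)
    out = []
    k = n_mhc
    for res in complex.peptide_residues:
        names = [a.name for a in res.atoms]
        side_idx = [i for i, n in enumerate(names) if n not in BACKBONE_ATOMS]
        if not side_idx:  # glycine: CA surrogate
            side_idx = [i for i, n in enumerate(names) if n == "CA"]
        in_complex = float(sum(per_atom[k + i] for i in side_idx))
        lone = Structure("ref", [("X", [res.copy()])])
        ref_atom = shrake_rupley(lone, probe, n_points)
        reference = float(sum(ref_atom[i] for i in side_idx))
        out.append(in_complex / reference if reference > 0 else 0.0)
        k += len(res.atoms)
    return np.array(out)


# ---------------------------------------------------------------------------
# TCR-face surface maps


def cleft_plane(complex: PMHCComplex) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the receptor C-alpha atoms.

    The normal is oriented toward the peptide centroid, i.e. "up" out of the
    cleft toward the TCR.
    """
    ca = np.array(list(complex.mhc_ca().values()))
    if len(ca) < 3:
        raise PmhcError("too few receptor C-alpha atoms to fit a cleft plane")
    origin = ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(ca - origin)
    normal = Vt[2]
    toward = complex.peptide.coords().mean(axis=0) - origin
    if np.dot(normal, toward) < 0:
        normal = -normal
    return origin, normal


def surface_potential(complex: PMHCComplex, probe: float = DEFAULT_PROBE,
                      n_points: int = DEFAULT_N_POINTS,
                      params: ScoringParams | None = None,
                      dielectric: str | None = None,
                      epsilon: float | None = None) -> SurfaceMap:
    """Electrostatic potential map over the TCR-facing accessible surface.

    Surface sample points whose outward normal has a positive component
    along the cleft-plane normal are retained; the Coulomb potential of the
    coarse formal charges is evaluated at each point (distance-dependent
    dielectric eps=4r by default, or constant-dielectric mode), converted to
    kT/e and clipped to +/-10.
    """
    params = _params(params)
    origin, normal = cleft_plane(complex)
    merged = _complex_structure(complex)
    pts, normals, _, _ = sas_points(merged, probe, n_points)
    upward = normals @ normal > 0.0
    if not np.any(upward):
        raise PmhcError("empty TCR-face region")
    pts = pts[upward]

    charges = assign_charges(merged, params)
    charged = np.abs(charges) > 1e-12
    values = np.zeros(len(pts))
    if np.any(charged):
        qpos = merged.coords()[charged]
        q = charges[charged]
        d = np.linalg.norm(pts[:, None, :] - qpos[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        mode = dielectric or params.dielectric_mode
        if mode == "distance":
            phi = params.coulomb_k * np.sum(q / (params.dielectric_factor * d * d), axis=1)
        else:
            eps = epsilon if epsilon is not None else params.dielectric_constant
            phi = params.coulomb_k * np.sum(q / (eps * d), axis=1)
        values = phi / KT_KCAL
    values = np.clip(values, -POTENTIAL_CLIP, POTENTIAL_CLIP)
    heights = (pts - origin) @ normal
    return SurfaceMap(pts, values, heights, origin, normal)


def compare_surfaces(a: SurfaceMap, b: SurfaceMap, capture_radius: float = 1.5):
    """Nearest-point matching between two maps in a common frame.

    Returns (topology_rms, potential_rms, matched_fraction): RMS height and
    potential differences over matched pairs, and the fraction of points in
    ``a`` that found a partner within ``capture_radius``.
    """
    tree = cKDTree(b.points)
    dist, idx = tree.query(a.points, distance_upper_bound=capture_radius)
    matched = np.isfinite(dist)
    if not np.any(matched):
        raise PmhcError("no surface points matched within the capture radius")
    ia = np.nonzero(matched)[0]
    ib = idx[matched]
    topo = float(np.sqrt(np.mean((a.heights[ia] - b.heights[ib]) ** 2)))
    pot = float(np.sqrt(np.mean((a.values[ia] - b.values[ib]) ** 2)))
    return topo, pot, float(matched.mean())
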