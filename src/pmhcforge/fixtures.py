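"""Deterministic synthetic structures for building and testing without downloads.

The generator emulates the geometry that matters to the other modules rather
than MHC biology: an ideal-geometry extended peptide suspended in a groove
formed by a pseudo-atom floor and two walls.  Optional anchor "pockets" are
cages of pseudo atoms around a chosen side chain (emulating the deep anchor
pockets of a real cleft), and optional mid-cleft "bulge blockers" are wall
protrusions that force the peptide to arch above them, the way conserved
cleft tryptophans do in real alleles.  Every fixture is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FixtureError
from .modeling import build_backbone, build_sidechain, n_chi
from .structio import Atom, PMHCComplex, Residue, SCAFFOLD_RESNAME, Structure, ONE_TO_THREE

__all__ = [
    "FixtureSpec",
    "EXTENDED_PHI_PSI",
    "make_ideal_peptide",
    "make_toy_cleft",
    "make_pattern_population",
]

#: default backbone torsions: extended (beta-like) conformation
EXTENDED_PHI_PSI = (-140.0, 135.0)

#: largest pseudo-atom van der Waals radius in the scaffold (carbon)
_MAX_RADIUS = 1.7

_WALL_HEIGHT = 6.8


@dataclass
class FixtureSpec:
    """Parameters of a toy-cleft fixture.

    ``pocket_depths`` maps 1-based peptide positions to pocket depth in
    angstroms below the floor; ``wall_spacing`` is the center-to-center
    distance of the two walls.
    """

    seed: int = 0
    peptide_seq: str | None = "KAVYNFATM"
    pocket_depths: dict[int, float] = field(default_factory=dict)
    wall_spacing: float = 15.0
    bulge_blockers: bool = False
    noise_sigma: float = 0.0
    n_copies: int = 1
    peptide_height: float = 3.0

    def __post_init__(self):
        if self.wall_spacing <= 2 * _MAX_RADIUS:
            raise FixtureError(
                f"wall spacing {self.wall_spacing} must exceed twice the atom radius"
            )
        if self.noise_sigma < 0:
            raise FixtureError("noise_sigma must be >= 0")
        if self.n_copies < 1:
            raise FixtureError("n_copies must be >= 1")


def make_ideal_peptide(seq: str, backbone_spec: list[tuple[float, float]] | None = None,
                       chain_id: str = "C",
                       chis: list[tuple[float, ...]] | None = None) -> Structure:
    """Full heavy-atom peptide from ideal internal geometry; deterministic.

    ``backbone_spec`` gives per-residue (phi, psi); default is uniformly
    extended.  ``chis`` optionally fixes side-chain torsions per residue.
    The structure is flagged ``capped`` so no terminus charges are assigned.
    """
    seq = seq.strip().upper()
    for aa in seq:
        if aa not in ONE_TO_THREE:
            raise FixtureError(f"non-canonical residue {aa!r} in sequence")
    if backbone_spec is None:
        backbone_spec = [EXTENDED_PHI_PSI] * len(seq)
    for phi, psi in backbone_spec:
        if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
            raise FixtureError(f"phi/psi ({phi}, {psi}) outside (-180, 180]")
    frames = build_backbone(seq, list(backbone_spec))
    residues = []
    for i, (aa, frame) in enumerate(zip(seq, frames), start=1):
        code3 = ONE_TO_THREE[aa]
        atoms = [Atom(name, name[0], frame[name]) for name in ("N", "CA", "C", "O")]
        chi = None if chis is None else tuple(chis[i - 1])[: n_chi(code3)]
        atoms += build_sidechain(code3, frame, chi)
        residues.append(Residue(code3, i, "", atoms))
    return Structure("ideal_peptide", [(chain_id, residues)], metadata={"capped": True})


def _orient_peptide(peptide: Structure, height: float) -> Structure:
    """Rotate/translate so the chain runs along +x with side chains downward."""
    out = peptide.copy()
    residues = out.chains[0][1]
    ca = np.array([r.get("CA").pos for r in residues])
    center = ca.mean(axis=0)
    X = ca - center
    _, _, Vt = np.linalg.svd(X)
    R = Vt  # rows: principal axes
    if np.dot(ca[-1] - ca[0], R[0]) < 0:
        R = np.diag([-1.0, 1.0, -1.0]) @ R
    if np.linalg.det(R) < 0:
        R = np.diag([1.0, 1.0, -1.0]) @ R
    coords = (out.coords() - center) @ R.T
    out.set_coords(coords)

    # flip about the chain axis until the mid-chain side chain points down (-z)
    residues = out.chains[0][1]
    mid = residues[len(residues) // 2]
    ref = mid.get("CB") or mid.get("CA")
    if ref.pos[2] > mid.get("CA").pos[2]:
        flip = np.diag([1.0, -1.0, -1.0])
        out.set_coords(out.coords() @ flip.T)
    # lift so the lowest atom (side chains included) clears the floor plane z=0
    low_z = min(a.pos[2] for a in out.atoms)
    shift = np.array([0.0, 0.0, height - low_z])
    out.set_coords(out.coords() + shift)
    return out


def _tuck_sidechains(peptide: Structure, wall_spacing: float) -> None:
    """Rebuild side chains that would cross into a wall, trying chi1 staples.

    Deterministic: for each offending residue the chi1 staple minimizing the
    lateral (|y|) reach of the side chain is kept, remaining chis at 180.
    """
    from .modeling import CHI_STAPLES

    limit = wall_spacing / 2 - 3.0
    for res in peptide.chains[0][1]:
        side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
        if not side or n_chi(res.code3) == 0:
            continue
        reach = max(abs(a.pos[1]) for a in side)
        if reach <= limit:
            continue
        best_atoms, best_reach = None, reach
        for c1 in CHI_STAPLES:
            chis = (c1,) + (180.0,) * (n_chi(res.code3) - 1)
            trial = build_sidechain(res.code3, res, chis)
            trial_reach = max(abs(a.pos[1]) for a in trial)
            if trial_reach < best_reach:
                best_atoms, best_reach = trial, trial_reach
        if best_atoms is not None:
            res.atoms = [res.get(n) for n in ("N", "CA", "C", "O")] + best_atoms


def _grid(xs, ys, zs):
    pts = []
    for x in xs:
        for y in ys:
            for z in zs:
                pts.append((x, y, z))
    return pts


def make_toy_cleft(spec: FixtureSpec):
    """Build a pseudo-atom groove (floor + walls) with an optional peptide.

    Returns a :class:`PMHCComplex` when ``spec.peptide_seq`` is set, else the
    bare receptor :class:`Structure`.  Pockets are open-topped cages of
    pseudo atoms surrounding the side chain at the given position, reaching
    ``depth`` below the floor; blockers are two wall protrusions at
    mid-cleft, and the placed peptide arches above them.
    """
    for pos, depth in spec.pocket_depths.items():
        if depth > _WALL_HEIGHT:
            raise FixtureError(f"pocket depth {depth} at p{pos} exceeds wall height {_WALL_HEIGHT}")

    peptide = None
    if spec.peptide_seq is not None:
        peptide = _orient_peptide(make_ideal_peptide(spec.peptide_seq), spec.peptide_height)
        _tuck_sidechains(peptide, spec.wall_spacing)
        low_z = min(a.pos[2] for a in peptide.atoms)  # re-level after tucking
        peptide.set_coords(peptide.coords() + np.array([0.0, 0.0, spec.peptide_height - low_z]))
        ca = np.array([r.get("CA").pos for r in peptide.chains[0][1]])
        x_lo, x_hi = ca[:, 0].min() - 3.5, ca[:, 0].max() + 3.5
    else:
        x_lo, x_hi = -18.0, 18.0

    w = spec.wall_spacing
    step = 1.7
    xs = np.arange(x_lo, x_hi + step, step)
    ys = np.arange(-w / 2, w / 2 + 1e-6, step)
    wall_zs = np.arange(step, _WALL_HEIGHT + 1e-6, step)

    points: list[tuple[float, float, float]] = []
    floor_pts = _grid(xs, ys, [0.0])
    wall_pts = _grid(xs, [-w / 2, w / 2], wall_zs)

    pocket_pts: list[tuple[float, float, float]] = []
    carve_centers = []
    if peptide is not None:
        residues = peptide.chains[0][1]
        all_coords = peptide.coords()
        for pos, depth in sorted(spec.pocket_depths.items()):
            if not 1 <= pos <= len(residues):
                raise FixtureError(f"pocket position p{pos} outside peptide")
            res = residues[pos - 1]
            side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
            side_coords = np.array([a.pos for a in side]) if side else res.get("CA").pos[None]
            other_mask = np.ones(len(all_coords), dtype=bool)
            offset = sum(len(r.atoms) for r in residues[: pos - 1])
            for i, a in enumerate(res.atoms):
                if a.name not in ("N", "CA", "C", "O"):
                    other_mask[offset + i] = False
            other_coords = all_coords[other_mask]
            anchor = side[-1].pos if side else res.get("CA").pos
            axis_xy = np.array([anchor[0], anchor[1]])
            carve_centers.append(axis_xy)
            top = max(a.pos[2] for a in side) + 0.4 if side else res.get("CA").pos[2] - 1.0
            ring_r = 3.4
            candidates = []
            for z in np.arange(-depth, top, 1.3):
                nring = 12
                for k in range(nring):
                    ang = 2 * np.pi * (k + (0.5 if int(z / 1.3) % 2 else 0.0)) / nring
                    candidates.append((axis_xy[0] + ring_r * np.cos(ang),
                                       axis_xy[1] + ring_r * np.sin(ang), z))
            for rr in (0.0, 1.7):
                nb = 1 if rr == 0 else 6
                for k in range(nb):
                    ang = 2 * np.pi * k / nb
                    candidates.append((axis_xy[0] + rr * np.cos(ang),
                                       axis_xy[1] + rr * np.sin(ang), -depth - 1.0))
            # the cage is carved to fit the planted peptide: points that would
            # clash with neighboring residues (or touch the anchored side
            # chain itself) are dropped, occlusion is preserved by the rest
            for p in candidates:
                p_arr = np.asarray(p)
                if np.min(np.linalg.norm(other_coords - p_arr, axis=1)) < 3.1:
                    continue
                if side and np.min(np.linalg.norm(side_coords - p_arr, axis=1)) < 2.7:
                    continue
                pocket_pts.append(p)

    def carved(p):
        return any(np.hypot(p[0] - c[0], p[1] - c[1]) < 4.2 for c in carve_centers)

    points += [p for p in floor_pts if not carved(p)]
    points += wall_pts
    points += pocket_pts

    blocker_pts: list[tuple[float, float, float]] = []
    if spec.bulge_blockers:
        if peptide is not None:
            residues = peptide.chains[0][1]
            i_mid = min(6, len(residues)) - 1  # near p6-p7
            x_mid = 0.5 * (residues[i_mid].get("CA").pos[0] + residues[min(i_mid + 1, len(residues) - 1)].get("CA").pos[0])
        else:
            x_mid = 0.0
        for sgn in (-1.0, 1.0):
            for yy in (sgn * (w / 2 - 1.7), sgn * (w / 2 - 3.4)):
                for zz in (2.4, 3.8):
                    blocker_pts.append((x_mid, yy, zz))
        points += blocker_pts

    residues_r = [Residue(SCAFFOLD_RESNAME, i + 1, "", [Atom("CA", "C", np.array(p))])
                  for i, p in enumerate(points)]
    receptor = Structure("toy_cleft", [("A", residues_r)],
                         metadata={"capped": True, "synthetic": True})

    if peptide is None:
        return receptor

    if spec.bulge_blockers:
        # arch the peptide over the blockers with a smooth vertical bump
        coords = peptide.coords()
        bump = 1.8 * np.exp(-((coords[:, 0] - x_mid) ** 2) / (2 * 2.5**2))
        coords[:, 2] += bump
        peptide.set_coords(coords)

    provenance = {
        "generator": "make_toy_cleft",
        "seed": spec.seed,
        "peptide_seq": spec.peptide_seq,
        "pocket_depths": dict(spec.pocket_depths),
        "bulge_blockers": spec.bulge_blockers,
        "planted_truth": True,
    }
    return PMHCComplex(receptor, peptide, provenance=provenance)


def make_pattern_population(base: PMHCComplex, n_copies: int, noise_sigma: float,
                            seed: int) -> list[PMHCComplex]:
    """Independent Gaussian coordinate noise on the peptide; receptor untouched."""
    if n_copies < 1:
        raise FixtureError("n_copies must be >= 1")
    if noise_sigma < 0:
        raise FixtureError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_copies):
        c = base.copy()
        coords = c.peptide.coords()
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
        c.peptide.set_coords(coords)
        c.provenance = dict(c.provenance, copy_index=k, noise_sigma=noise_sigma, seed=seed)
        out.append(c)
    return out
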