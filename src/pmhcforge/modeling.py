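"""Template threading, ideal-geometry side-chain construction, and minimization.

Threading copies the template backbone verbatim (N, CA, C, O) and rebuilds
side chains for the target sequence from an ideal internal-coordinate table;
positions where target and template residues coincide keep the template's
side-chain atoms.  The resulting model typically has a few strained contacts,
which a short steepest-descent minimization relaxes.

The minimizer drives the :mod:`energetics` potential with soft geometry
restraints: 1-2 and 1-3 interatomic distances are harmonically tethered to
their input values, so covalent geometry is preserved while torsions stay
free.  Accepted steps are found by backtracking line search, making the
energy trace non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .energetics import InternalPotential, ScoringParams
from .errors import PmhcError, ThreadingError
from .geometry import dihedral, place_atom
from .structio import Atom, PMHCComplex, Residue, Structure, ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "RotamerSpec",
    "EMTrace",
    "geometry_table",
    "chi_atom_names",
    "n_chi",
    "rotamer_library",
    "chi_staples",
    "build_sidechain",
    "measure_chis",
    "build_backbone",
    "thread_sequence",
    "minimize",
    "CHI_STAPLES",
]

#: canonical chi staple values (degrees) used for rotamer construction
CHI_STAPLES = (-60.0, 180.0, 60.0)

#: sp2 branches prefer perpendicular / eclipsed staples over sp3 gauche/trans
_RING_CHI2 = {"PHE", "TYR", "TRP", "HIS"}
_AMIDE_TERMINAL = {"ASN": 1, "ASP": 1, "GLN": 2, "GLU": 2}  # chi index of the sp2 branch


def chi_staples(code3: str, chi_index: int) -> tuple[float, ...]:
    """Staple values sampled for one chi of one residue type."""
    if chi_index == 1 and code3 in _RING_CHI2:
        return (90.0, -90.0)
    if _AMIDE_TERMINAL.get(code3) == chi_index:
        return (0.0, 90.0, -90.0)
    if chi_index >= 2:
        return (180.0, -60.0, 60.0)
    return CHI_STAPLES

_GEOMETRY: dict | None = None


def geometry_table() -> dict:
    """The packaged ideal side-chain internal-coordinate table."""
    global _GEOMETRY
    if _GEOMETRY is None:
        text = resources.files("pmhcforge.data").joinpath("sidechain_geometry.json").read_text()
        _GEOMETRY = json.loads(text)
    return _GEOMETRY


def chi_atom_names(code3: str) -> list[tuple[str, str, str, str]]:
    spec = geometry_table()["residues"].get(code3)
    if spec is None:
        return []
    return [tuple(q) for q in spec["chi_atoms"]]


def n_chi(code3: str) -> int:
    return len(chi_atom_names(code3))


@dataclass
class RotamerSpec:
    """Canonical rotamers for one residue type: chi angle tuples in degrees."""

    code3: str
    rotamers: list[tuple[float, ...]]

    def __post_init__(self):
        if not self.rotamers:
            raise PmhcError(f"{self.code3}: rotamer list must be non-empty")
        for rot in self.rotamers:
            for chi in rot:
                if not -180.0 < chi <= 180.0:
                    raise PmhcError(f"{self.code3}: chi {chi} outside (-180, 180]")


def rotamer_library() -> dict[str, RotamerSpec]:
    """Minimal backbone-independent rotamer library from chi staples.

    The first two chis take all three staples; deeper chis are held at 180 to
    keep the library small (the docking sampler jitters every chi anyway).
    """
    lib = {}
    for code3 in geometry_table()["residues"]:
        nchis = n_chi(code3)
        if nchis == 0:
            lib[code3] = RotamerSpec(code3, [()])
            continue
        rots = [()]
        for depth in range(nchis):
            staples = chi_staples(code3, depth) if depth < 2 else chi_staples(code3, depth)[:1]
            rots = [r + (s,) for r in rots for s in staples]
        lib[code3] = RotamerSpec(code3, rots)
    return lib


def build_sidechain(code3: str, backbone: dict[str, np.ndarray] | Residue,
                    chis: tuple[float, ...] | None = None) -> list[Atom]:
    """Place side-chain heavy atoms from ideal internal geometry.

    ``backbone`` supplies the N/CA/C frame (a Residue or a name->coord map);
    ``chis`` are the chi torsions in degrees (default: first canonical
    rotamer, -60/180/...).  Glycine yields an empty list.
    """
    spec = geometry_table()["residues"].get(code3)
    if spec is None:
        raise ThreadingError(f"non-canonical residue {code3!r}")
    if isinstance(backbone, Residue):
        frame = {n: backbone.get(n).pos for n in ("N", "CA", "C") if backbone.get(n) is not None}
    else:
        frame = dict(backbone)
    for req in ("N", "CA", "C"):
        if req not in frame:
            raise PmhcError(f"backbone frame missing atom {req}")
    nchis = len(spec["chi_atoms"])
    if chis is None:
        chis = tuple(chi_staples(code3, k)[0] for k in range(nchis))
    if len(chis) != nchis:
        raise PmhcError(f"{code3}: expected {nchis} chi angles, got {len(chis)}")

    placed: dict[str, np.ndarray] = dict(frame)
    atoms: list[Atom] = []
    for name, (a, b, c), bond, angle, chi_idx, offset in spec["atoms"]:
        torsion = offset if chi_idx is None else chis[chi_idx] + offset
        pos = place_atom(placed[a], placed[b], placed[c], bond, angle, torsion)
        placed[name] = pos
        atoms.append(Atom(name, name[0], pos))
    return atoms


def measure_chis(residue: Residue) -> list[float]:
    """Chi torsions (degrees) measured from a residue's coordinates."""
    out = []
    for quad in chi_atom_names(residue.code3):
        atoms = [residue.get(n) for n in quad]
        if any(a is None for a in atoms):
            break
        out.append(dihedral(*(a.pos for a in atoms)))
    return out


# ---------------------------------------------------------------------------
# backbone construction (shared with the fixture generator)


def build_backbone(seq: str, phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with the given phi/psi.

    The first residue's phi is unused; omega is held at 180.  Returns one
    name->coord map per residue.
    """
    bb = geometry_table()["backbone"]
    n = len(seq)
    if len(phi_psi) != n:
        raise PmhcError("phi/psi list length must match sequence length")
    frames: list[dict[str, np.ndarray]] = []
    for i in range(n):
        phi = phi_psi[i][0]
        if i == 0:
            N = np.zeros(3)
            CA = np.array([bb["N_CA"], 0.0, 0.0])
            C = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, bb["CA_C"], bb["N_CA_C"], phi)
        else:
            prev = frames[-1]
            psi_prev = phi_psi[i - 1][1]
            N = place_atom(prev["N"], prev["CA"], prev["C"], bb["C_N"], bb["CA_C_N"], psi_prev)
            CA = place_atom(prev["CA"], prev["C"], N, bb["N_CA"], bb["C_N_CA"], bb["omega"])
            C = place_atom(prev["C"], N, CA, bb["CA_C"], bb["N_CA_C"], phi)
        frames.append({"N": N, "CA": CA, "C": C})
    for i, frame in enumerate(frames):
        psi = phi_psi[i][1]
        frame["O"] = place_atom(frame["N"], frame["CA"], frame["C"], bb["C_O"], bb["CA_C_O"],
                                psi + 180.0)
    return frames


# ---------------------------------------------------------------------------
# threading


def _template_residues(template) -> list[Residue]:
    if isinstance(template, PMHCComplex):
        return template.peptide_residues
    if isinstance(template, Structure):
        if len(template.chains) != 1:
            raise ThreadingError("template structure must be a single peptide chain")
        return template.chains[0][1]
    return list(template)


def thread_sequence(target_seq: str, template, chain_id: str | None = None) -> Structure:
    """Thread a target sequence onto a template peptide backbone.

    The backbone is copied verbatim; identical residues keep the template
    side chain, substituted residues get an ideal-geometry side chain at the
    default rotamer.  Lengths must match and every residue (target and
    template) must be canonical.
    """
    template_res = _template_residues(template)
    target_seq = target_seq.strip().upper()
    if len(target_seq) != len(template_res):
        raise ThreadingError(
            f"target length {len(target_seq)} != template length {len(template_res)}; "
            "threading requires a template with the same number of residues"
        )
    out_residues = []
    for i, (aa, tres) in enumerate(zip(target_seq, template_res), start=1):
        if aa not in ONE_TO_THREE:
            raise ThreadingError(f"non-canonical target residue {aa!r} at p{i}")
        if not tres.is_canonical:
            raise ThreadingError(
                f"template residue {tres.code3} at p{i} is non-canonical; refusing to thread"
            )
        code3 = ONE_TO_THREE[aa]
        backbone_atoms = [tres.get(n).copy() for n in ("N", "CA", "C", "O")]
        if any(a is None for a in backbone_atoms):
            raise ThreadingError(f"template residue at p{i} lacks a complete backbone")
        if code3 == tres.code3:
            new = tres.copy()
        else:
            side = build_sidechain(code3, tres)
            new = Residue(code3, tres.seqnum, tres.icode, backbone_atoms + side)
        out_residues.append(new)
    cid = chain_id or (_chain_id_of(template) or "P")
    return Structure("threaded", [(cid, out_residues)], metadata={"capped": True})


def _chain_id_of(template) -> str | None:
    if isinstance(template, PMHCComplex):
        return template.peptide.chains[0][0]
    if isinstance(template, Structure) and template.chains:
        return template.chains[0][0]
    return None


# ---------------------------------------------------------------------------
# minimization


@dataclass
class EMTrace:
    """Energy trajectory of a minimization run (accepted steps only)."""

    steps: list[tuple[int, float]] = field(default_factory=list)
    nsteps_requested: int = 0
    converged: bool = False

    @property
    def energies(self) -> list[float]:
        return [e for _, e in self.steps]


class _RestrainedObjective:
    """InternalPotential plus harmonic 1-2 / 1-3 distance restraints."""

    K_BOND = 300.0  # score units per square angstrom
    K_ANGLE = 60.0

    def __init__(self, structure: Structure, params: ScoringParams | None, restrain: bool):
        self.pot = InternalPotential(structure, params)
        self.restrain = restrain
        coords0 = structure.coords()
        bonds = self.pot.bonds
        neigh: dict[int, set[int]] = {}
        for i, j in bonds:
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
        bond_set = {tuple(sorted(b)) for b in bonds}
        # scaffold pseudo-atoms are tethered in place: they represent a rigid
        # environment with no internal degrees of freedom worth relaxing
        from .energetics import scaffold_mask

        self.tethered = np.nonzero(scaffold_mask(structure))[0]
        self.tether_pos = coords0[self.tethered].copy() if len(self.tethered) else np.empty((0, 3))
        self.K_TETHER = 50.0
        one_three = set()
        for j, nb in neigh.items():
            for i in nb:
                for k in nb:
                    if i < k and (i, k) not in bond_set:
                        one_three.add((i, k))
        bond_list, angle_list = sorted(bond_set), sorted(one_three)
        self.r_pairs = np.array(bond_list + angle_list, dtype=int).reshape(-1, 2)
        self.r_k = np.array([self.K_BOND] * len(bond_list) + [self.K_ANGLE] * len(angle_list))
        if len(self.r_pairs):
            d = coords0[self.r_pairs[:, 0]] - coords0[self.r_pairs[:, 1]]
            self.r_target = np.linalg.norm(d, axis=1)
        else:
            self.r_target = np.empty(0)

    def __call__(self, coords: np.ndarray, with_gradient: bool = False):
        if with_gradient:
            breakdown, grad = self.pot.gradient(coords)
        else:
            breakdown = self.pot.energy(coords)
        total = breakdown.total
        if self.restrain and len(self.r_pairs):
            d = coords[self.r_pairs[:, 0]] - coords[self.r_pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dev = r - self.r_target
            total += float(np.sum(self.r_k * dev**2))
            if with_gradient:
                f = (2.0 * self.r_k * dev / np.maximum(r, 1e-9))[:, None] * d
                np.add.at(grad, self.r_pairs[:, 0], f)
                np.add.at(grad, self.r_pairs[:, 1], -f)
        if self.restrain and len(self.tethered):
            dpos = coords[self.tethered] - self.tether_pos
            total += float(self.K_TETHER * np.sum(dpos**2))
            if with_gradient:
                grad[self.tethered] += 2.0 * self.K_TETHER * dpos
        if with_gradient:
            return breakdown, total, grad
        return breakdown, total


def minimize(structure: Structure, nsteps: int = 100,
             fixed: np.ndarray | list[int] | None = None,
             params: ScoringParams | None = None,
             restrain_geometry: bool = True,
             gtol: float = 1e-3,
             max_step: float = 0.1) -> tuple[Structure, EMTrace]:
    """Steepest-descent relaxation with backtracking line search.

    ``fixed`` marks immobile atoms (indices or boolean mask over the
    structure's atom list).  The trace records accepted energies only, so it
    is non-increasing; convergence is declared when the gradient norm of the
    mobile atoms drops below ``gtol`` or no decreasing step can be found.
    """
    if nsteps < 1:
        raise PmhcError("nsteps must be >= 1")
    out = structure.copy()
    coords = out.coords()
    n = len(coords)
    mobile = np.ones(n, dtype=bool)
    if fixed is not None:
        fixed = np.asarray(fixed)
        if fixed.dtype == bool:
            mobile = ~fixed
        else:
            mobile[fixed.astype(int)] = False

    objective = _RestrainedObjective(out, params, restrain_geometry)
    trace = EMTrace(nsteps_requested=nsteps)

    breakdown, energy, grad = objective(coords, with_gradient=True)
    if not np.isfinite(energy):
        raise PmhcError("initial energy is not finite; aborting minimization")
    trace.steps.append((0, energy))

    if not mobile.any():
        trace.converged = True
        out.set_coords(coords)
        return out, trace

    for step in range(1, nsteps + 1):
        grad[~mobile] = 0.0
        gnorm = float(np.sqrt(np.sum(grad**2)))
        if gnorm <= gtol:
            trace.converged = True
            break
        direction = -grad
        gmax = np.abs(direction).max()
        alpha = max_step / gmax if gmax > 0 else 0.0
        improved = False
        for _ in range(16):
            trial = coords + alpha * direction
            _, e_trial = objective(trial)
            if np.isfinite(e_trial) and e_trial < energy:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            trace.converged = gnorm <= gtol
            break
        coords = trial
        breakdown, energy, grad = objective(coords, with_gradient=True)
        trace.steps.append((step, energy))
    else:
        grad[~mobile] = 0.0
        trace.converged = float(np.sqrt(np.sum(grad**2))) <= gtol

    out.set_coords(coords)
    return out, trace
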