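"""A lightweight empirical potential for scoring peptide poses and driving EM.

Four pairwise-additive terms over heavy atoms, in arbitrary "score units":

* steric: 12-6 Lennard-Jones, ``4 eps ((sigma/r)^12 - (sigma/r)^6)`` with
  ``sigma`` the sum of the two element radii;
* electrostatic: Coulomb on coarse formal charges with a distance-dependent
  dielectric (``eps = 4 r`` by default), or constant-dielectric mode;
* hbond: a 10-4 well between donor (N, hydroxyl O) and acceptor (O) heavy
  atoms, depth at ``r0 = 2.9`` angstrom, weighted by ``cos^2`` of the
  antecedent-donor-acceptor angle (zero below 90 degrees);
* torsion: a 3-fold staple penalty ``k (1 + cos 3 chi)`` on side-chain chi
  torsions, with minima at the -60/+60/180 rotamer staples.

Interactions are truncated sharply at the cutoff (8 angstrom default).  The
docking engine treats these scores as its objective; they are deliberately
not calibrated to any physical kcal/mol scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .errors import ScoringError
from .geometry import dihedral
from .structio import BACKBONE_ATOMS, SCAFFOLD_RESNAME, Structure


def scaffold_mask(structure: Structure) -> np.ndarray:
    """Per-atom flag marking synthetic scaffold pseudo-atoms."""
    return np.array([res.code3 == SCAFFOLD_RESNAME
                     for res in structure.residues for _ in res.atoms], dtype=bool)

__all__ = [
    "EnergyBreakdown",
    "ScoringParams",
    "default_params",
    "assign_charges",
    "score_pose",
    "internal_energy",
    "InternalPotential",
]

#: hydroxyl/thiol-like oxygens that act as both donor and acceptor
_HYDROXYL = {"OG", "OG1", "OH"}


@dataclass
class EnergyBreakdown:
    steric: float = 0.0
    hbond: float = 0.0
    electrostatic: float = 0.0
    torsion: float = 0.0

    @property
    def total(self) -> float:
        return self.steric + self.hbond + self.electrostatic + self.torsion

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.steric + other.steric,
            self.hbond + other.hbond,
            self.electrostatic + other.electrostatic,
            self.torsion + other.torsion,
        )

    def as_dict(self) -> dict:
        return {
            "steric": self.steric,
            "hbond": self.hbond,
            "electrostatic": self.electrostatic,
            "torsion": self.torsion,
            "total": self.total,
        }


@dataclass
class ScoringParams:
    lj: dict = field(default_factory=dict)  # element -> {radius, eps}
    hbond_r0: float = 2.9
    hbond_eps: float = 2.0
    coulomb_k: float = 332.06
    dielectric_mode: str = "distance"  # "distance" (eps = factor * r) or "constant"
    dielectric_factor: float = 4.0
    dielectric_constant: float = 80.0
    cutoff: float = 8.0
    torsion_k: float = 0.5
    charges: dict = field(default_factory=dict)  # code3 -> {atom -> q}
    terminus_charge: float = 1.0

    @classmethod
    def from_json(cls, text: str) -> "ScoringParams":
        raw = json.loads(text)
        return cls(
            lj=raw["lj"],
            hbond_r0=raw["hbond"]["r0"],
            hbond_eps=raw["hbond"]["eps"],
            coulomb_k=raw["coulomb_k"],
            dielectric_mode=raw["dielectric"]["mode"],
            dielectric_factor=raw["dielectric"]["factor"],
            dielectric_constant=raw["dielectric"]["constant"],
            cutoff=raw["cutoff"],
            torsion_k=raw["torsion_k"],
            charges=raw["charges"],
            terminus_charge=raw["terminus_charge"],
        )

    def __post_init__(self):
        for el, p in self.lj.items():
            if p["radius"] <= 0:
                raise ScoringError(f"non-positive LJ radius for element {el}")
        if self.cutoff <= 0:
            raise ScoringError("cutoff must be positive")

    def lj_for(self, element: str) -> tuple[float, float]:
        p = self.lj.get(element)
        if p is None:
            raise ScoringError(f"no Lennard-Jones parameters for element {element!r}")
        return p["radius"], p["eps"]


def default_params() -> ScoringParams:
    text = resources.files("pmhcforge.data").joinpath("scoring_params.json").read_text()
    return ScoringParams.from_json(text)


_DEFAULT: ScoringParams | None = None


def _params(params: ScoringParams | None) -> ScoringParams:
    global _DEFAULT
    if params is not None:
        return params
    if _DEFAULT is None:
        _DEFAULT = default_params()
    return _DEFAULT


# ---------------------------------------------------------------------------
# per-atom annotation


def assign_charges(structure: Structure, params: ScoringParams | None = None,
                   include_termini: bool | None = None) -> np.ndarray:
    """Coarse formal charge per atom (K/R +1, D/E -1 split, H +0.1 split).

    Chain termini carry +1 (N) / -1 (carboxylate O) unless the structure is
    flagged ``capped`` in its metadata (synthetic fixtures are built capped)
    or ``include_termini=False``.
    """
    params = _params(params)
    if include_termini is None:
        include_termini = not structure.metadata.get("capped", False)
    q = []
    for _, residues in structure.chains:
        protein = [r for r in residues if r.get("CA") is not None]
        first = protein[0] if protein else None
        last = protein[-1] if protein else None
        for res in residues:
            table = params.charges.get(res.code3, {})
            for atom in res.atoms:
                charge = table.get(atom.name, 0.0)
                if include_termini and res is first and atom.name == "N":
                    charge += params.terminus_charge
                if include_termini and res is last and atom.name in ("O", "OXT"):
                    n_oxy = 2 if res.get("OXT") is not None else 1
                    charge -= params.terminus_charge / n_oxy
                q.append(charge)
    return np.array(q, dtype=float)


def _donor_acceptor_flags(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    donor, acceptor = [], []
    for res in structure.residues:
        for atom in res.atoms:
            is_hydroxyl = atom.name in _HYDROXYL
            donor.append(atom.element == "N" or is_hydroxyl)
            acceptor.append(atom.element == "O")
    return np.array(donor), np.array(acceptor)


def detect_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds inferred from interatomic distances.

    Pairs within one residue closer than 1.95 angstrom (2.1 if sulfur is
    involved) are bonded; between sequence-adjacent residues only the peptide
    bond C(i)-N(i+1) is considered.  Topology is inferred once from the input
    coordinates and then held fixed.
    """
    bonds: list[tuple[int, int]] = []
    offset = 0
    for _, residues in structure.chains:
        res_atoms = []
        for res in residues:
            idx = list(range(offset, offset + len(res.atoms)))
            res_atoms.append((res, idx))
            offset += len(res.atoms)
        for ri, (res, idx) in enumerate(res_atoms):
            for (a, i) in zip(res.atoms, idx):
                for (b, j) in zip(res.atoms, idx):
                    if j <= i:
                        continue
                    limit = 2.1 if "S" in (a.element, b.element) else 1.95
                    if np.linalg.norm(a.pos - b.pos) < limit:
                        bonds.append((i, j))
            if ri + 1 < len(res_atoms):
                nres, nidx = res_atoms[ri + 1]
                ci = next((i for a, i in zip(res.atoms, idx) if a.name == "C"), None)
                nj = next((j for b, j in zip(nres.atoms, nidx) if b.name == "N"), None)
                if ci is not None and nj is not None:
                    c_atom = res.get("C")
                    n_atom = nres.get("N")
                    if np.linalg.norm(c_atom.pos - n_atom.pos) < 1.95:
                        bonds.append((ci, nj))
    return bonds


def _exclusions(n_atoms: int, bonds: list[tuple[int, int]]) -> set[tuple[int, int]]:
    neigh: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        neigh[i].add(j)
        neigh[j].add(i)
    excl = {tuple(sorted(b)) for b in bonds}
    for j, nb in neigh.items():
        for i in nb:
            for k in nb:
                if i < k:
                    excl.add((i, k))
    return excl


def _antecedents(coords: np.ndarray, bonds: list[tuple[int, int]]) -> np.ndarray:
    """Index of the nearest bonded heavy neighbor per atom (-1 if none)."""
    ante = np.full(len(coords), -1, dtype=int)
    best = np.full(len(coords), np.inf)
    for i, j in bonds:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < best[i]:
            best[i], ante[i] = d, j
        if d < best[j]:
            best[j], ante[j] = d, i
    return ante


def _chi_quadruples(structure: Structure) -> list[tuple[int, int, int, int]]:
    from .modeling import chi_atom_names  # data table lives with the builder

    quads = []
    offset = 0
    for res in structure.residues:
        names = {a.name: offset + k for k, a in enumerate(res.atoms)}
        for quad in chi_atom_names(res.code3):
            if all(n in names for n in quad):
                quads.append(tuple(names[n] for n in quad))
        offset += len(res.atoms)
    return quads


# ---------------------------------------------------------------------------
# pairwise evaluation


class _PairTerms:
    """Vectorized pair-term evaluation over fixed atom annotations."""

    def __init__(self, elements, charges, donor, acceptor, antecedent, params: ScoringParams):
        self.params = params
        radii_eps = [params.lj_for(e) for e in elements]
        self.radius = np.array([r for r, _ in radii_eps])
        self.eps = np.array([e for _, e in radii_eps])
        self.q = np.asarray(charges, float)
        self.donor = np.asarray(donor, bool)
        self.acceptor = np.asarray(acceptor, bool)
        self.antecedent = np.asarray(antecedent, int)

    def evaluate(self, coords: np.ndarray, pairs_i: np.ndarray, pairs_j: np.ndarray,
                 with_gradient: bool = False):
        p = self.params
        coords = np.asarray(coords, float)
        if pairs_i.size == 0:
            zero = EnergyBreakdown()
            return (zero, np.zeros_like(coords)) if with_gradient else zero
        dvec = coords[pairs_j] - coords[pairs_i]
        r = np.linalg.norm(dvec, axis=1)
        keep = (r <= p.cutoff) & (r > 1e-6)
        pairs_i, pairs_j, dvec, r = pairs_i[keep], pairs_j[keep], dvec[keep], r[keep]

        sigma = self.radius[pairs_i] + self.radius[pairs_j]
        eps = np.sqrt(self.eps[pairs_i] * self.eps[pairs_j])
        s6 = (sigma / r) ** 6
        e_lj = 4.0 * eps * (s6 * s6 - s6)
        dlj_dr = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r

        qq = self.q[pairs_i] * self.q[pairs_j]
        if p.dielectric_mode == "distance":
            e_el = p.coulomb_k * qq / (p.dielectric_factor * r * r)
            del_dr = -2.0 * e_el / r
        else:
            e_el = p.coulomb_k * qq / (p.dielectric_constant * r)
            del_dr = -e_el / r

        hb_mask = ((self.donor[pairs_i] & self.acceptor[pairs_j])
                   | (self.donor[pairs_j] & self.acceptor[pairs_i]))
        e_hb = np.zeros_like(r)
        dhb_dr = np.zeros_like(r)
        if np.any(hb_mask):
            idx = np.nonzero(hb_mask)[0]
            t = p.hbond_r0 / r[idx]
            radial = (p.hbond_eps / 6.0) * (4.0 * t**10 - 10.0 * t**4)
            dradial = (p.hbond_eps / 6.0) * (-40.0 * t**10 + 40.0 * t**4) / r[idx]
            i_arr, j_arr = pairs_i[idx], pairs_j[idx]
            don_is_i = self.donor[i_arr] & self.acceptor[j_arr]
            dn = np.where(don_is_i, i_arr, j_arr)
            ac = np.where(don_is_i, j_arr, i_arr)
            a = self.antecedent[dn]
            w = np.ones(len(idx))
            valid = a >= 0
            if np.any(valid):
                u = coords[a[valid]] - coords[dn[valid]]
                v = coords[ac[valid]] - coords[dn[valid]]
                cosang = (np.sum(u * v, axis=1)
                          / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)))
                # theta >= 90 deg <=> cos(theta) <= 0
                w[valid] = np.where(cosang <= 0.0, cosang**2, 0.0)
            e_hb[idx] = radial * w
            dhb_dr[idx] = dradial * w  # angle factor held fixed in the gradient

        breakdown = EnergyBreakdown(float(e_lj.sum()), float(e_hb.sum()), float(e_el.sum()), 0.0)
        if not with_gradient:
            return breakdown
        dE_dr = dlj_dr + del_dr + dhb_dr
        grad = np.zeros_like(coords)
        unit = dvec / r[:, None]
        contrib = dE_dr[:, None] * unit
        np.add.at(grad, pairs_i, -contrib)
        np.add.at(grad, pairs_j, contrib)
        return breakdown, grad


def _annotate(structure: Structure, params: ScoringParams):
    atoms = structure.atoms
    elements = [a.element for a in atoms]
    coords = structure.coords()
    bonds = detect_bonds(structure)
    donor, acceptor = _donor_acceptor_flags(structure)
    charges = assign_charges(structure, params)
    ante = _antecedents(coords, bonds)
    return elements, coords, bonds, donor, acceptor, charges, ante


def score_pose(receptor: Structure, peptide: Structure,
               params: ScoringParams | None = None) -> EnergyBreakdown:
    """Interaction energy between receptor and peptide (no internal terms)."""
    params = _params(params)
    er, cr, br, dr, ar, qr, antr = _annotate(receptor, params)
    ep, cp, bp, dp, ap, qp, antp = _annotate(peptide, params)
    nr = len(cr)
    elements = er + ep
    coords = np.vstack([cr, cp]) if len(cp) else cr
    donor = np.concatenate([dr, dp])
    acceptor = np.concatenate([ar, ap])
    charges = np.concatenate([qr, qp])
    ante = np.concatenate([antr, np.where(antp >= 0, antp + nr, -1)])
    terms = _PairTerms(elements, charges, donor, acceptor, ante, params)

    tree_r = cKDTree(cr)
    tree_p = cKDTree(cp)
    sparse = tree_r.sparse_distance_matrix(tree_p, params.cutoff, output_type="coo_matrix")
    pairs_i = sparse.row
    pairs_j = sparse.col + nr
    return terms.evaluate(coords, pairs_i, pairs_j)


class InternalPotential:
    """Intra-structure potential: nonbonded pairs (1-2/1-3 excluded) + chi staples.

    Topology (bonds, exclusions, donor antecedents, chi quadruples) is frozen
    from the construction-time coordinates; the energy and gradient are then
    functions of a flat (n, 3) coordinate array, which is what the steepest-
    descent minimizer iterates on.
    """

    def __init__(self, structure: Structure, params: ScoringParams | None = None):
        self.params = _params(params)
        (self.elements, self.coords0, self.bonds, donor, acceptor,
         charges, ante) = _annotate(structure, self.params)
        self.n = len(self.coords0)
        self.excluded = _exclusions(self.n, self.bonds)
        self._excl_keys = np.fromiter((i * self.n + j for i, j in sorted(self.excluded)),
                                      dtype=np.int64, count=len(self.excluded))
        # scaffold pseudo-atoms are inert among themselves: they represent a
        # rigid environment, not a molecule
        self.scaffold = scaffold_mask(structure)
        self.terms = _PairTerms(self.elements, charges, donor, acceptor, ante, self.params)
        self.chi_quads = _chi_quadruples(structure)

    def _pairs(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tree = cKDTree(coords)
        raw = tree.query_pairs(self.params.cutoff, output_type="ndarray")
        if raw.size == 0:
            return np.empty(0, int), np.empty(0, int)
        keys = raw[:, 0].astype(np.int64) * self.n + raw[:, 1]
        keep = ~np.isin(keys, self._excl_keys, assume_unique=False)
        keep &= ~(self.scaffold[raw[:, 0]] & self.scaffold[raw[:, 1]])
        raw = raw[keep]
        return raw[:, 0], raw[:, 1]

    def _torsion_energy(self, coords: np.ndarray) -> float:
        k = self.params.torsion_k
        e = 0.0
        for (i, j, l, m) in self.chi_quads:
            chi = dihedral(coords[i], coords[j], coords[l], coords[m])
            e += k * (1.0 + np.cos(np.deg2rad(3.0 * chi)))
        return e

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        pi, pj = self._pairs(coords)
        breakdown = self.terms.evaluate(coords, pi, pj)
        breakdown.torsion = self._torsion_energy(coords)
        return breakdown

    def gradient(self, coords: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
        pi, pj = self._pairs(coords)
        breakdown, grad = self.terms.evaluate(coords, pi, pj, with_gradient=True)
        breakdown.torsion = self._torsion_energy(coords)
        # chi torsions involve only 4 atoms each; local central differences
        h = 1e-5
        k = self.params.torsion_k
        for quad in self.chi_quads:
            for idx in quad:
                for dim in range(3):
                    for sgn in (+1, -1):
                        coords[idx, dim] += sgn * h
                        chi = dihedral(*(coords[q] for q in quad))
                        e = k * (1.0 + np.cos(np.deg2rad(3.0 * chi)))
                        grad[idx, dim] += sgn * e / (2 * h)
                        coords[idx, dim] -= sgn * h
        return breakdown, grad


def internal_energy(structure: Structure, params: ScoringParams | None = None) -> EnergyBreakdown:
    """Nonbonded self-energy (1-2 and 1-3 pairs excluded) plus the chi staple term."""
    pot = InternalPotential(structure, params)
    return pot.energy(structure.coords())
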