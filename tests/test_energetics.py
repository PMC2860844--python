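import numpy as np
import pytest

from pmhcforge.energetics import (
    EnergyBreakdown,
    assign_charges,
    default_params,
    detect_bonds,
    internal_energy,
    score_pose,
)
from pmhcforge.errors import ScoringError
from pmhcforge.fixtures import make_ideal_peptide
from pmhcforge.geometry import rotation_about_axis
from pmhcforge.structio import Atom, Residue, Structure


def carbon(name, pos, chain="X", resname="UNK"):
    return Structure(name, [(chain, [Residue(resname, 1, "", [
        Atom(name, "C", np.asarray(pos, float))])])], metadata={"capped": True})


def brute_force_pose_energy(receptor, peptide, params):
    """Independent double loop over all atom pairs, no neighbor lists."""
    hydroxyl = {"OG", "OG1", "OH"}
    steric = elec = hbond = 0.0

    def annotations(structure):
        out = []
        charges = assign_charges(structure, params)
        k = 0
        for _, residues in structure.chains:
            for ri, res in enumerate(residues):
                for atom in res.atoms:
                    # covalent neighbors: same residue plus the peptide bond
                    candidates = [o for o in res.atoms if o is not atom]
                    if atom.name == "N" and ri > 0:
                        prev_c = residues[ri - 1].get("C")
                        if prev_c is not None:
                            candidates.append(prev_c)
                    if atom.name == "C" and ri + 1 < len(residues):
                        next_n = residues[ri + 1].get("N")
                        if next_n is not None:
                            candidates.append(next_n)
                    ante, best = None, np.inf
                    for other in candidates:
                        d = np.linalg.norm(other.pos - atom.pos)
                        if d < 1.95 and d < best:
                            best, ante = d, other.pos
                    out.append((atom, charges[k], ante,
                                atom.element == "N" or atom.name in hydroxyl,
                                atom.element == "O"))
                    k += 1
        return out

    for a, qa, antea, dona, acca in annotations(receptor):
        for b, qb, anteb, donb, accb in annotations(peptide):
            r = np.linalg.norm(a.pos - b.pos)
            if r > params.cutoff:
                continue
            sigma = params.lj_for(a.element)[0] + params.lj_for(b.element)[0]
            eps = np.sqrt(params.lj_for(a.element)[1] * params.lj_for(b.element)[1])
            s6 = (sigma / r) ** 6
            steric += 4 * eps * (s6 * s6 - s6)
            elec += params.coulomb_k * qa * qb / (params.dielectric_factor * r * r)
            pairs = []
            if dona and accb:
                pairs.append((a, antea, b))
            elif donb and acca:
                pairs.append((b, anteb, a))
            for dn, ante, ac in pairs:
                t = params.hbond_r0 / r
                radial = (params.hbond_eps / 6.0) * (4 * t**10 - 10 * t**4)
                w = 1.0
                if ante is not None:
                    u, v = ante - dn.pos, ac.pos - dn.pos
                    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    w = cos**2 if cos <= 0 else 0.0
                hbond += radial * w
    return steric, hbond, elec


class TestScorePose:
    def test_beyond_cutoff_all_zero(self, toy_cleft):
        far = toy_cleft.peptide.copy()
        far.set_coords(far.coords() + np.array([500.0, 0.0, 0.0]))
        bd = score_pose(toy_cleft.mhc, far)
        assert bd.steric == bd.hbond == bd.electrostatic == bd.total == 0.0

    def test_clash_dominates(self):
        bd = score_pose(carbon("a", [0, 0, 0]), carbon("b", [0.5, 0, 0], chain="Y"))
        assert bd.steric > 1e6
        assert bd.total == pytest.approx(bd.steric, rel=1e-6)

    def test_matches_brute_force_double_loop(self):
        receptor = make_ideal_peptide("NST", chain_id="R")
        peptide = make_ideal_peptide("KDE", chain_id="P")
        peptide.metadata["capped"] = False  # termini charged: exercises electrostatics
        shifted = peptide.copy()
        shifted.set_coords(shifted.coords() + np.array([0.0, 4.5, 1.0]))
        params = default_params()
        bd = score_pose(receptor, shifted, params)
        steric, hbond, elec = brute_force_pose_energy(receptor, shifted, params)
        assert bd.steric == pytest.approx(steric, abs=1e-9)
        assert bd.hbond == pytest.approx(hbond, abs=1e-9)
        assert bd.electrostatic == pytest.approx(elec, abs=1e-9)

    def test_symmetric_in_arguments(self, toy_cleft):
        a = score_pose(toy_cleft.mhc, toy_cleft.peptide)
        b = score_pose(toy_cleft.peptide, toy_cleft.mhc)
        assert a.total == pytest.approx(b.total, abs=1e-9)

    def test_invariant_under_joint_rigid_motion(self, toy_cleft):
        before = score_pose(toy_cleft.mhc, toy_cleft.peptide)
        R = rotation_about_axis([1, 1, 0], 33.0)
        t = np.array([2.0, -3.0, 4.0])
        mhc, pep = toy_cleft.mhc.copy(), toy_cleft.peptide.copy()
        mhc.set_coords(mhc.coords() @ R.T + t)
        pep.set_coords(pep.coords() @ R.T + t)
        after = score_pose(mhc, pep)
        assert after.total == pytest.approx(before.total, abs=1e-9)

    def test_unknown_element_named_in_error(self):
        weird = Structure("w", [("X", [Residue("UNK", 1, "", [
            Atom("XE1", "Xe", np.zeros(3))])])])
        with pytest.raises(ScoringError, match="Xe"):
            score_pose(weird, carbon("b", [3.0, 0, 0], chain="Y"))

    def test_monotone_repulsion_below_minimum(self):
        energies = [score_pose(carbon("a", [0, 0, 0]),
                               carbon("b", [d, 0, 0], chain="Y")).steric
                    for d in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)]
        assert all(a > b for a, b in zip(energies, energies[1:]))


class TestInternalEnergy:
    def test_single_atom_zero(self):
        assert internal_energy(carbon("a", [0, 0, 0])).total == 0.0

    def test_deterministic_across_runs(self):
        dipeptide = make_ideal_peptide("AA")
        values = {internal_energy(dipeptide).total for _ in range(3)}
        assert len(values) == 1

    def test_breakdown_sums_to_total(self):
        bd = internal_energy(make_ideal_peptide("KDYE"))
        assert bd.total == pytest.approx(
            bd.steric + bd.hbond + bd.electrostatic + bd.torsion, abs=1e-9)

    def test_bonded_and_angle_pairs_excluded(self):
        """1-2 and 1-3 pairs contribute nothing: a lone alanine scores ~0."""
        ala = make_ideal_peptide("A")
        bd = internal_energy(ala)
        # only 1-4+ pairs remain (e.g. O..CB), all modest
        assert abs(bd.steric) < 10.0

    def test_matches_brute_force_pairs(self):
        pep = make_ideal_peptide("SNA")
        params = default_params()
        bonds = detect_bonds(pep)
        neighbors = {}
        for i, j in bonds:
            neighbors.setdefault(i, set()).add(j)
            neighbors.setdefault(j, set()).add(i)
        excluded = set(map(tuple, map(sorted, bonds)))
        for m, nb in neighbors.items():
            for i in nb:
                for k in nb:
                    if i < k:
                        excluded.add((i, k))
        atoms = pep.atoms
        steric = 0.0
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                if (i, j) in excluded:
                    continue
                r = np.linalg.norm(atoms[i].pos - atoms[j].pos)
                if r > params.cutoff:
                    continue
                sigma = params.lj_for(atoms[i].element)[0] + params.lj_for(atoms[j].element)[0]
                eps = np.sqrt(params.lj_for(atoms[i].element)[1] * params.lj_for(atoms[j].element)[1])
                s6 = (sigma / r) ** 6
                steric += 4 * eps * (s6 * s6 - s6)
        assert internal_energy(pep).steric == pytest.approx(steric, abs=1e-9)


def test_energy_breakdown_addition():
    a = EnergyBreakdown(1.0, 2.0, 3.0, 4.0)
    b = EnergyBreakdown(0.5, 0.5, 0.5, 0.5)
    assert (a + b).total == pytest.approx(12.0)


def test_charge_assignment_rules():
    pep = make_ideal_peptide("KDAH")
    pep.metadata["capped"] = False
    q = assign_charges(pep)
    names = [(r.code3, a.name) for r in pep.residues for a in r.atoms]
    charge = dict(zip(names, q))
    assert charge[("LYS", "NZ")] == pytest.approx(1.0)
    assert charge[("ASP", "OD1")] == pytest.approx(-0.5)
    assert charge[("LYS", "N")] == pytest.approx(1.0)  # N terminus
    assert charge[("HIS", "O")] == pytest.approx(-1.0)  # C terminus
    assert charge[("HIS", "ND1")] == pytest.approx(0.05)
    # capped fixture peptides carry no terminus charges
    pep.metadata["capped"] = True
    q2 = assign_charges(pep)
    charge2 = dict(zip(names, q2))
    assert charge2[("LYS", "N")] == 0.0
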