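import numpy as np
import pytest

from pmhcforge.docking import (
    ConformerPopulation,
    ProtocolConfig,
    run_d1_em_d2,
    sample_conformers,
    select_representative,
)
from pmhcforge.energetics import EnergyBreakdown, detect_bonds
from pmhcforge.errors import PmhcError, ThreadingError
from pmhcforge.fixtures import FixtureSpec, make_toy_cleft
from pmhcforge.structio import Atom, Residue, Structure
from pmhcforge.superpose import fit_by_mhc_ca, rmsd_between


def pose_at(offset):
    """Minimal 3-atom rigid pose used to construct synthetic populations."""
    atoms = [Atom(n, "C", np.array([x + offset, 0.0, 0.0]))
             for n, x in (("C1", 0.0), ("C2", 1.5), ("C3", 3.0))]
    return Structure("pose", [("P", [Residue("UNK", 1, "", atoms)])])


def population(offsets_energies):
    return ConformerPopulation(conformers=[
        (pose_at(off), EnergyBreakdown(steric=e)) for off, e in offsets_energies
    ])


class TestSelectRepresentative:
    def test_frequency_beats_global_best_energy(self):
        """8 poses near zero vs 2 distant poses holding the global best."""
        pop = population([(0.0, -5.0), (0.1, -4.0), (0.05, -4.5), (0.15, -3.5),
                         (0.02, -4.2), (0.12, -3.9), (0.08, -4.1), (0.03, -4.4),
                         (10.0, -9.0), (10.1, -8.5)])
        rep = select_representative(pop, cluster_rmsd=1.0)
        assert pose_at(0.0).coords()[0][0] - 1 < pop.conformers[rep][0].coords()[0][0] < 1.0
        members, _ = pop.clusters[0]
        assert len(members) == 8

    def test_single_conformer_selects_itself(self):
        pop = population([(0.0, 1.0)])
        assert select_representative(pop) == 0

    def test_equal_size_clusters_lower_energy_wins(self):
        pop = population([(0.0, -1.0), (0.1, -0.5), (10.0, -3.0), (10.1, -0.2)])
        rep = select_representative(pop, cluster_rmsd=1.0)
        assert pop.conformers[rep][0].coords()[0][0] >= 9.0
        assert pop.conformers[rep][1].total == -3.0

    def test_energy_first_mode(self):
        pop = population([(0.0, -5.0), (0.1, -4.0), (0.05, -4.5),
                         (10.0, -9.0)])
        rep = select_representative(pop, cluster_rmsd=1.0, frequency_first=False)
        assert pop.conformers[rep][1].total == -9.0

    def test_clusters_partition_population(self):
        pop = population([(float(i) * 0.2, -float(i)) for i in range(10)])
        select_representative(pop, cluster_rmsd=0.5)
        seen = sorted(m for members, _ in pop.clusters for m in members)
        assert seen == list(range(10))

    def test_empty_population_rejected(self):
        with pytest.raises(PmhcError):
            select_representative(ConformerPopulation())


class TestSampleConformers:
    def test_degenerate_sampler_yields_identical_poses(self, toy_cleft):
        config = ProtocolConfig(n_runs=1, n_out_per_run=5, iterations=5,
                                translation_amplitude=0.0, rotation_amplitude=0.0,
                                chi_jitter=0.0, sample_sidechains=False)
        rng = np.random.default_rng(0)
        pop = sample_conformers(toy_cleft.mhc, toy_cleft.peptide, config, rng)
        energies = pop.energies()
        assert np.all(energies == energies[0])
        for pose, _ in pop.conformers:
            np.testing.assert_array_equal(pose.coords(), toy_cleft.peptide.coords())

    def test_fixed_seed_bit_identical(self, toy_cleft):
        config = ProtocolConfig(n_runs=1, n_out_per_run=8, iterations=12)
        pops = [sample_conformers(toy_cleft.mhc, toy_cleft.peptide, config,
                                  np.random.default_rng(42)) for _ in range(2)]
        for (pa, ea), (pb, eb) in zip(*[p.conformers for p in pops]):
            np.testing.assert_array_equal(pa.coords(), pb.coords())
            assert ea.total == eb.total

    def test_native_pose_wins_on_planted_landscape(self, toy_cleft_pocket):
        """After relaxation (as in the protocol), the pocket-anchored native
        pose scores best and its cluster provides the representative."""
        from pmhcforge.modeling import minimize

        cx = toy_cleft_pocket
        relaxed, _ = minimize(cx.peptide, nsteps=100)
        config = ProtocolConfig(n_runs=1, n_out_per_run=20, iterations=40)
        pop = sample_conformers(cx.mhc, relaxed, config, np.random.default_rng(3))
        rep = select_representative(pop)
        rep_pose = pop.conformers[rep][0]
        assert rmsd_between(rep_pose.coords(), relaxed.coords()) < 1.0

    def test_receptor_never_mutated(self, toy_cleft):
        before = toy_cleft.mhc.coords().copy()
        config = ProtocolConfig(n_runs=1, n_out_per_run=5, iterations=8)
        sample_conformers(toy_cleft.mhc, toy_cleft.peptide, config,
                          np.random.default_rng(1))
        np.testing.assert_array_equal(toy_cleft.mhc.coords(), before)

    def test_backbone_geometry_untouched_by_sampling(self, toy_cleft):
        config = ProtocolConfig(n_runs=1, n_out_per_run=5, iterations=10)
        pop = sample_conformers(toy_cleft.mhc, toy_cleft.peptide, config,
                                np.random.default_rng(5))
        ref = toy_cleft.peptide

        def bond_lengths(structure):
            coords = structure.coords()
            return np.array(sorted(np.linalg.norm(coords[i] - coords[j])
                                   for i, j in detect_bonds(structure)
                                   if structure.atoms[i].name in ("N", "CA", "C", "O")
                                   and structure.atoms[j].name in ("N", "CA", "C", "O")))

        for pose, _ in pop.conformers:
            np.testing.assert_allclose(bond_lengths(pose), bond_lengths(ref), atol=1e-9)


class TestProtocol:
    def test_self_reconstruction_within_bound(self, toy_cleft, small_config):
        result = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft,
                              small_config)
        _, rmsd = fit_by_mhc_ca(result.complex, toy_cleft)
        assert rmsd <= 1.0

    def test_identical_seeds_identical_results(self, toy_cleft):
        config = ProtocolConfig(n_runs=2, n_out_per_run=8, iterations=12,
                                em_short=30, em_long=60, seed=9)
        a = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft, config)
        b = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft, config)
        np.testing.assert_array_equal(a.complex.to_structure().coords(),
                                      b.complex.to_structure().coords())
        assert a.d2_energy.total == b.d2_energy.total

    def test_length_mismatch_rejected(self, toy_cleft, small_config):
        with pytest.raises(ThreadingError):
            run_d1_em_d2("KAVYNFAT", toy_cleft, toy_cleft, small_config)

    def test_allele_mismatch_rejected(self, toy_cleft, small_config):
        donor = toy_cleft.copy()
        donor.provenance["allele"] = "H-2Db"
        template = toy_cleft.copy()
        template.provenance["allele"] = "HLA-A*0201"
        with pytest.raises(PmhcError, match="allele"):
            run_d1_em_d2(toy_cleft.peptide_sequence, donor, template, small_config)

    def test_backbone_bonds_drift_below_tolerance(self, toy_cleft, small_config):
        result = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft,
                              small_config)
        for res_in, res_out in zip(toy_cleft.peptide_residues,
                                   result.complex.peptide_residues):
            for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
                d_in = np.linalg.norm(res_in.get(a).pos - res_in.get(b).pos)
                d_out = np.linalg.norm(res_out.get(a).pos - res_out.get(b).pos)
                assert abs(d_in - d_out) < 0.05

    def test_receptor_rigid_during_docking(self, toy_cleft, small_config):
        """Receptor moves only in the complex EM, never in D1/D2 sampling."""
        before = toy_cleft.mhc.coords().copy()
        result = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft,
                              small_config)
        np.testing.assert_array_equal(toy_cleft.mhc.coords(), before)
        # final receptor comes from the EM stage; scaffold tethering keeps it close
        drift = np.abs(result.complex.mhc.coords() - before).max()
        assert drift < 0.5

    def test_provenance_complete(self, toy_cleft, small_config):
        result = run_d1_em_d2(toy_cleft.peptide_sequence, toy_cleft, toy_cleft,
                              small_config)
        prov = result.complex.provenance
        assert {"template", "donor", "target_seq", "seed", "protocol"} <= set(prov)
        assert prov["seed"] == small_config.seed
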