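import numpy as np
import pytest

from pmhcforge.datasets import h2db_ligands
from pmhcforge.errors import PmhcError
from pmhcforge.fixtures import FixtureSpec, make_ideal_peptide, make_pattern_population, make_toy_cleft
from pmhcforge.patterns import (
    burial_profile,
    composition_at,
    conserved_contact_report,
    deviation_from_pattern,
    extract_pattern,
)
from pmhcforge.structio import Atom, PMHCComplex, Residue, Structure


class TestExtractPattern:
    def test_identical_copies_have_zero_dispersion(self, toy_cleft):
        pop = make_pattern_population(toy_cleft, 5, 0.0, seed=1)
        pat = extract_pattern(pop)
        np.testing.assert_allclose(pat.dispersion, 0.0, atol=1e-9)
        backbone = np.array([[r.get(n).pos for n in ("N", "CA", "C", "O")]
                             for r in toy_cleft.peptide_residues])
        np.testing.assert_allclose(pat.mean_coords, backbone, atol=1e-9)

    def test_single_member_pattern_is_own_backbone(self, toy_cleft):
        pat = extract_pattern([toy_cleft])
        np.testing.assert_allclose(pat.dispersion, 0.0, atol=1e-12)
        assert pat.members == [str(toy_cleft.provenance.get("source", toy_cleft.mhc.id) or "complex")] \
            or len(pat.members) == 1

    def test_gaussian_noise_dispersion_matches_expectation(self, toy_cleft):
        """sigma=0.3 per coordinate gives per-atom RMS deviation ~ sigma*sqrt(3)."""
        pop = make_pattern_population(toy_cleft, 1000, 0.3, seed=3)
        pat = extract_pattern(pop)
        assert np.mean(pat.dispersion) == pytest.approx(0.3 * np.sqrt(3.0), rel=0.02)

    def test_permutation_invariant(self, toy_cleft, rng):
        pop = make_pattern_population(toy_cleft, 8, 0.2, seed=5)
        pat_a = extract_pattern(pop)
        order = rng.permutation(len(pop))
        # keep the same frame member first so the common frame is unchanged
        shuffled = [pop[0]] + [pop[i] for i in order if i != 0]
        pat_b = extract_pattern(shuffled)
        np.testing.assert_allclose(pat_a.mean_coords, pat_b.mean_coords, atol=1e-9)
        np.testing.assert_allclose(pat_a.dispersion, pat_b.dispersion, atol=1e-9)

    def test_adding_mean_conformation_never_increases_dispersion(self, toy_cleft):
        """Duplicating the central (mean) conformation tightens every position."""
        pop = make_pattern_population(toy_cleft, 6, 0.25, seed=9)
        pat = extract_pattern(pop)
        central = pop[0].copy()
        mean_pep = np.mean([c.peptide.coords() for c in pop], axis=0)
        central.peptide.set_coords(mean_pep)
        pat_more = extract_pattern([pop[0]] + pop[1:] + [central])
        assert np.all(pat_more.dispersion <= pat.dispersion + 1e-9)

    def test_mixed_alleles_rejected(self, toy_cleft):
        a, b = toy_cleft.copy(), toy_cleft.copy()
        a.provenance["allele"] = "H-2Db"
        b.provenance["allele"] = "H-2Kb"
        with pytest.raises(PmhcError, match="mixed alleles"):
            extract_pattern([a, b])

    def test_mixed_lengths_split_per_length_with_warning(self, toy_cleft):
        ten = make_toy_cleft(FixtureSpec(peptide_seq="SQLKNNAKEI"))
        with pytest.warns(UserWarning, match="mixed peptide lengths"):
            patterns = extract_pattern([toy_cleft, ten])
        assert set(patterns) == {9, 10}


class TestDeviation:
    def test_member_is_not_an_exception(self, toy_cleft):
        pop = make_pattern_population(toy_cleft, 20, 0.2, seed=2)
        pat = extract_pattern(pop)
        rep = deviation_from_pattern(pat, pop[0])
        assert not rep.exception
        member_devs = [deviation_from_pattern(pat, c).overall_backbone_rmsd for c in pop]
        assert rep.overall_backbone_rmsd <= max(member_devs)

    def test_identical_to_mean_gives_zero(self, toy_cleft):
        pat = extract_pattern(make_pattern_population(toy_cleft, 4, 0.0, seed=0))
        rep = deviation_from_pattern(pat, toy_cleft)
        assert rep.overall_backbone_rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rep.per_position, 0.0, atol=1e-9)

    def test_planted_p5_bulge_is_flagged(self, toy_cleft):
        pat = extract_pattern(make_pattern_population(toy_cleft, 10, 0.2, seed=4))
        outlier = toy_cleft.copy()
        res5 = outlier.peptide_residues[4]
        for atom in res5.atoms:  # p5 rises out of the cleft
            atom.pos = atom.pos + np.array([0.0, 0.0, 4.0])
        rep = deviation_from_pattern(pat, outlier)
        assert rep.exception
        assert rep.worst_position == 5

    def test_length_mismatch_rejected(self, toy_cleft):
        pat = extract_pattern([toy_cleft])
        ten = make_toy_cleft(FixtureSpec(peptide_seq="SQLKNNAKEI"))
        with pytest.raises(PmhcError, match="length"):
            deviation_from_pattern(pat, ten)


@pytest.fixture(scope="module")
def curated():
    return [(r.pdb_code, r.sequence) for r in h2db_ligands(distinct_only=True)]


class TestComposition:
    def test_p5_anchor_strongly_prefers_asparagine(self, curated):
        table = composition_at(curated, 5)
        assert table.total == 28
        assert table.counts["N"] == 25
        non_asn = {code for code, seq in curated if seq[4] != "N"}
        assert non_asn == {"1INQ", "1JUF", "1BZ9"}

    def test_cterm_anchor_nonpolar_with_single_cysteine(self, curated):
        table = composition_at(curated, -1)
        assert table.class_counts["nonpolar"] == 27
        assert table.counts.get("C", 0) == 1
        cys = {code for code, seq in curated if seq[-1] == "C"}
        assert cys == {"1FG2"}

    def test_single_sequence(self):
        table = composition_at([("x", "AAAA")], 2)
        assert table.counts == {"A": 1}

    def test_class_counts_partition_total(self, curated):
        for pos in (1, 2, 5, -1):
            table = composition_at(curated, pos)
            assert sum(table.class_counts.values()) == table.total

    def test_empty_input_rejected(self):
        with pytest.raises(PmhcError):
            composition_at([], 1)


class TestBurial:
    def test_free_peptide_all_exposed(self, toy_cleft):
        free = PMHCComplex(Structure("none", []), toy_cleft.peptide.copy())
        assert all(label == "exposed" for _, _, label in burial_profile(free))

    def test_deep_p5_pocket_buries_anchor(self, toy_cleft_pocket):
        profile = burial_profile(toy_cleft_pocket)
        assert profile[4][2] == "buried"

    def test_occlusion_only_removes_area(self, toy_cleft):
        free = PMHCComplex(Structure("none", []), toy_cleft.peptide.copy())
        rel_free = np.array([v for _, v, _ in burial_profile(free)])
        rel_cleft = np.array([v for _, v, _ in burial_profile(toy_cleft)])
        assert np.all(rel_cleft <= rel_free + 1e-9)


class TestConservedContacts:
    def _complex_with_ser73(self, distance):
        """Toy receptor carrying a serine-like donor near the p5 carbonyl O."""
        pep = make_ideal_peptide("AAAAAAAAA")
        target = pep.chains[0][1][4].get("O").pos
        direction = np.array([0.0, 1.0, 0.3])
        direction /= np.linalg.norm(direction)
        og = target + distance * direction
        cb = og + 1.43 * direction  # CB-OG-O angle = 180 degrees
        ca = cb + 1.53 * direction
        ser = Residue("SER", 73, "", [Atom("CA", "C", ca), Atom("CB", "C", cb),
                                      Atom("OG", "O", og)])
        filler = [Residue("ALA", i, "", [Atom("CA", "C", np.array([i * 3.0, 8.0, 0.0]))])
                  for i in range(1, 5)]
        mhc = Structure("toy", [("A", filler + [ser])])
        return PMHCComplex(mhc, pep, provenance={"source": "toy"})

    def test_hbond_inside_criterion_reported(self):
        reports = conserved_contact_report([self._complex_with_ser73(2.9)], 73)
        assert reports[0].residue == "SER"
        contacts = [(p, ma) for p, ma, _, _ in reports[0].hbonds]
        assert (5, "OG") in contacts

    def test_distance_outside_criterion_not_reported(self):
        reports = conserved_contact_report([self._complex_with_ser73(4.0)], 73)
        assert all(not (p == 5 and ma == "OG" and pa == "O")
                   for p, ma, pa, _ in reports[0].hbonds)

    def test_missing_residue_warns_not_fatal(self, toy_cleft):
        reports = conserved_contact_report([toy_cleft], 9999)
        assert reports[0].residue is None
        assert reports[0].warning
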