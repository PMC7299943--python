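"""G, A, H matrices and the pairwise kinship estimator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinpred import relmat
from kinpred.relmat import (
    DEGREE_MZ,
    DEGREE_UNRELATED,
    KinshipEstimate,
    RelationshipMatrix,
    RelmatError,
    classify_degree,
    compute_a_matrix,
    compute_grm,
    compute_h_matrix,
    estimate_kinship,
    pairwise_kinship,
)
from kinpred.simdata import (
    GenotypeMatrix,
    SimulationConfig,
    generate_pedigree,
    simulate_genotypes,
    unrelated_pedigree,
)

from .oracles import ibd_relationship_oracle


def _geno(dosages, freqs=None):
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    ids = np.array([f"I{i}" for i in range(n)], dtype=object)
    snps = np.array([f"S{j}" for j in range(m)], dtype=object)
    return GenotypeMatrix(ids, snps, dosages, freqs)


class TestGrm:
    def test_single_snp_hand_example(self):
        """M=1, dosages (0,1,2), p=0.5: standardized column is
        (-sqrt(2), 0, sqrt(2)); G has diagonal (2, 0, 2) and G_13 = -2."""
        g = compute_grm(_geno([[0], [1], [2]]))
        np.testing.assert_allclose(np.diag(g.values), [2.0, 0.0, 2.0], atol=1e-12)
        assert g.values[0, 2] == pytest.approx(-2.0)

    def test_identical_rows_have_equal_relationship(self):
        g = compute_grm(_geno([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]]))
        assert g.values[0, 1] == pytest.approx(g.values[0, 0])
        assert g.values[0, 0] == pytest.approx(g.values[1, 1])

    def test_mean_diagonal_is_one_for_unrelated(self):
        ped = unrelated_pedigree(500)
        cfg = SimulationConfig(n_snps=5000, seed=11)
        g = compute_grm(simulate_genotypes(ped, cfg))
        assert np.diag(g.values).mean() == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_snp_rejected_with_name(self):
        with pytest.raises(ValueError, match="S1"):
            compute_grm(_geno([[0, 2], [1, 2], [2, 2]]))

    def test_raw_mode_uses_dosages_verbatim(self):
        d = np.array([[0, 1], [2, 1]])
        g = compute_grm(_geno(d), standardize=False)
        np.testing.assert_allclose(g.values, d @ d.T / 2.0)

    def test_missing_imputed_to_2p(self):
        d = np.array([[0, 1], [2, -1], [1, 0], [1, 1]])
        g = compute_grm(_geno(d, freqs=np.array([0.5, 0.4])))
        # imputation makes the standardized entry 0, so I1's relationship
        # with itself only counts the first SNP
        w = (2 - 1.0) / np.sqrt(2 * 0.5 * 0.5)
        assert g.values[1, 1] == pytest.approx(w * w / 2.0)


class TestAmatrix:
    def test_one_recursion_step(self, toy_pedigrees):
        a = compute_a_matrix(toy_pedigrees["nuclear"])
        assert a.submatrix(["P1"], ["S1"])[0, 0] == pytest.approx(0.5)
        assert a.submatrix(["S1"], ["S2"])[0, 0] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(a.values), 1.0)

    def test_inbred_offspring_diagonal(self, toy_pedigrees):
        """Offspring of a parent-offspring mating: F = 0.25, a_ii = 1.25."""
        a = compute_a_matrix(toy_pedigrees["inbred"])
        assert a.submatrix(["D"], ["D"])[0, 0] == pytest.approx(1.25)

    def test_half_sibs(self, toy_pedigrees):
        a = compute_a_matrix(toy_pedigrees["half_sibs"])
        assert a.submatrix(["K1"], ["K2"])[0, 0] == pytest.approx(0.25)

    def test_first_cousins(self, toy_pedigrees):
        a = compute_a_matrix(toy_pedigrees["cousins"])
        assert a.submatrix(["FAM0000_G2S0C0"], ["FAM0000_G2S1C1"])[0, 0] == (
            pytest.approx(0.125)
        )

    @pytest.mark.parametrize(
        "name", ["trio", "nuclear", "half_sibs", "inbred", "cousins"]
    )
    def test_agrees_with_gene_dropping_ibd_oracle(self, toy_pedigrees, name):
        """Tabular-method A equals brute-force IBD sharing on every bundled
        pedigree."""
        ped = toy_pedigrees[name]
        a = compute_a_matrix(ped)
        oracle = ibd_relationship_oracle(ped, n_rep=100_000, seed=1)
        assert np.abs(a.values - oracle).max() < 0.01

    def test_founders_identity_block(self, toy_pedigrees):
        a = compute_a_matrix(toy_pedigrees["trio"])
        block = a.submatrix(["P1", "P2"])
        np.testing.assert_allclose(block, np.eye(2))


class TestHmatrix:
    @pytest.fixture(scope="class")
    def family_data(self):
        cfg = SimulationConfig(n_families=12, sibship_size=3, n_snps=800, seed=17)
        ped = generate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        return ped, geno

    def test_all_genotyped_collapses_to_g(self, family_data):
        ped, geno = family_data
        a = compute_a_matrix(ped)
        g = compute_grm(geno)
        h = compute_h_matrix(a, g, list(g.ids))
        assert np.abs(h.values - g.submatrix(list(a.ids))).max() < 1e-10

    def test_g_equal_a22_collapses_to_a(self, family_data):
        ped, geno = family_data
        a = compute_a_matrix(ped)
        gset = [i for i in a.ids if i.endswith("S0") or i.endswith("S1")]
        fake_g = RelationshipMatrix(
            np.array(gset, dtype=object), a.submatrix(gset), "G"
        )
        h = compute_h_matrix(a, fake_g, gset)
        assert np.abs(h.values - a.values).max() < 1e-10

    def test_three_individual_block_arithmetic(self):
        """Two genotyped founders, one ungenotyped offspring: H matches a
        direct evaluation of the printed block formulas."""
        import pandas as pd

        from kinpred.simdata import Pedigree, UNKNOWN

        ped = Pedigree(pd.DataFrame(
            [("F1", UNKNOWN, UNKNOWN, "M", "X", 0),
             ("F2", UNKNOWN, UNKNOWN, "F", "X", 0),
             ("C", "F1", "F2", "M", "X", 1)],
            columns=list(Pedigree.COLUMNS),
        ))
        a = compute_a_matrix(ped)
        gv = np.array([[1.05, -0.10], [-0.10, 0.93]])
        g = RelationshipMatrix(np.array(["F1", "F2"], dtype=object), gv, "G")
        h = compute_h_matrix(a, g, ["F1", "F2"])
        # direct block arithmetic, partition (ungenotyped C | genotyped F1 F2)
        a11 = np.array([[1.0]])
        a12 = np.array([[0.5, 0.5]])
        a22 = np.eye(2)
        a22i = np.linalg.inv(a22)
        h11 = a11 + a12 @ a22i @ (gv - a22) @ a22i @ a12.T
        h12 = a12 @ a22i @ gv
        expect = np.block([[h11, h12], [h12.T, gv]])
        got = h.submatrix(["C", "F1", "F2"])
        assert np.abs(got - expect).max() < 1e-10

    def test_h22_block_is_exactly_g(self, family_data):
        ped, geno = family_data
        a = compute_a_matrix(ped)
        gset = [i for i in a.ids if not i.endswith("G0M")]
        g = compute_grm(geno.subset(ids=gset))
        h = compute_h_matrix(a, g, gset)
        np.testing.assert_array_equal(h.submatrix(gset), g.values)

    def test_singular_a22_suggests_blending(self):
        import pandas as pd

        from kinpred.simdata import Pedigree, UNKNOWN

        # identical twin founders duplicated as two records make A22 singular
        ped = Pedigree(pd.DataFrame(
            [("F1", UNKNOWN, UNKNOWN, "M", "X", 0),
             ("F2", UNKNOWN, UNKNOWN, "F", "X", 0),
             ("C", "F1", "F2", "M", "X", 1)],
            columns=list(Pedigree.COLUMNS),
        ))
        a = compute_a_matrix(ped)
        sing = a.values.copy()
        sing[0, 1] = sing[1, 0] = 1.0  # F1 == F2 duplicates
        a_bad = RelationshipMatrix(a.ids, sing, "A")
        g = RelationshipMatrix(
            np.array(["F1", "F2"], dtype=object), np.eye(2) * 1.01, "G"
        )
        with pytest.raises(RelmatError, match="blend"):
            compute_h_matrix(a_bad, g, ["F1", "F2"])


class TestKinship:
    def test_identical_individuals_are_mz(self):
        row = np.array([0, 1, 2, 1, 0, 1] * 20)
        geno = _geno(np.vstack([row, row]))
        est = estimate_kinship(geno, "I0", "I1")
        assert est.phi == pytest.approx(0.5)
        assert est.degree == DEGREE_MZ

    def test_opposite_homozygotes_without_hets_error(self):
        a = np.array([0] * 120)
        b = np.array([2] * 120)
        with pytest.raises(RelmatError, match="heterozygous"):
            estimate_kinship(_geno(np.vstack([a, b])), "I0", "I1")

    def test_hand_counts(self):
        """N_Aa,Aa=50, N_AA,aa=10, N_Aa(i)=120, N_Aa(j)=80 gives
        phi = (50-20)/200 = 0.15, second degree."""
        gi = np.concatenate([
            np.ones(50), np.ones(70), np.zeros(30), np.zeros(10), np.zeros(40)
        ]).astype(np.int8)
        gj = np.concatenate([
            np.ones(50), np.zeros(70), np.ones(30), np.full(10, 2), np.zeros(40)
        ]).astype(np.int8)
        est = estimate_kinship(_geno(np.vstack([gi, gj])), "I0", "I1")
        assert est.phi == pytest.approx(0.15)
        assert est.degree == "2"

    def test_too_few_shared_snps(self):
        geno = _geno(np.array([[1] * 50, [1] * 50]))
        with pytest.raises(RelmatError, match="100"):
            estimate_kinship(geno, "I0", "I1")

    def test_parent_offspring_phi_near_quarter(self):
        cfg = SimulationConfig(n_families=40, sibship_size=1, n_snps=4000, seed=23)
        ped = generate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        phis = [
            estimate_kinship(geno, f"FAM{f:04d}_G0M", f"FAM{f:04d}_G1S0").phi
            for f in range(40)
        ]
        assert np.mean(phis) == pytest.approx(0.25, abs=0.03)

    def test_pairwise_matches_single_pair_estimator(self, small_dataset):
        _, _, geno = small_dataset
        sub = geno.subset(ids=list(geno.ids[:12]))
        mat = pairwise_kinship(sub)
        for i in range(0, 12, 5):
            for j in range(i + 1, 12, 3):
                est = estimate_kinship(sub, sub.ids[i], sub.ids[j])
                # pairwise path counts in float32; agreement to 1e-5 suffices
                assert mat[i, j] == pytest.approx(est.phi, abs=1e-5)


class TestClassifyDegree:
    @pytest.mark.parametrize(
        "phi, degree",
        [
            (0.5, DEGREE_MZ),
            (0.25, "1"),
            (0.125, "2"),
            (0.0625, "3"),
            (0.01, DEGREE_UNRELATED),
            # boundaries are upper-inclusive: ties go to the higher degree
            (0.3536, "1"),
            (0.1768, "2"),
            (0.0884, "3"),
            (0.0442, "3"),
        ],
    )
    def test_threshold_table(self, phi, degree):
        assert classify_degree(phi) == degree

    def test_boundary_0442_is_third_degree_not_unrelated(self):
        assert classify_degree(0.0442) == "3"
        assert classify_degree(0.0441) == DEGREE_UNRELATED

    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_total_and_consistent(self, phi):
        """Every finite phi maps to exactly one label, consistent with the
        threshold table."""
        label = classify_degree(phi)
        if phi > 0.3536:
            assert label == DEGREE_MZ
        elif phi >= 0.0442:
            assert label in ("1", "2", "3")
        else:
            assert label == DEGREE_UNRELATED


class TestRelationshipMatrixContainer:
    def test_asymmetry_rejected(self):
        vals = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(RelmatError, match="symmetric"):
            RelationshipMatrix(np.array(["a", "b"], dtype=object), vals, "G")

    def test_tsv_round_trip_is_exact_at_12_digits(self, tmp_path, small_dataset):
        _, _, geno = small_dataset
        g = compute_grm(geno.subset(ids=list(geno.ids[:30])))
        path = tmp_path / "g.tsv"
        g.write_tsv(path, header_comment="roundtrip test")
        back = RelationshipMatrix.read_tsv(path)
        assert list(back.ids) == list(g.ids)
        assert back.kind == "G"
        np.testing.assert_allclose(back.values, g.values, rtol=1e-11, atol=1e-14)
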