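"""Estimator formulas, algebraic identities, KING counts, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ukin import (EstimatorConfig, GenotypeMatrix, KinshipMatrix,
                  classify_relationship, king_robust, read_grm_text,
                  read_kinship_matrix, rgrm, scgrm, ukin, ukin_per_snp,
                  write_grm_text, write_kinship_matrix)
from conftest import random_genotypes


def _geno(dosages, mask=None):
    d = np.asarray(dosages, dtype=np.int8)
    mask = np.zeros_like(d, bool) if mask is None else np.asarray(mask, bool)
    return GenotypeMatrix(d, mask,
                          [f"s{i}" for i in range(d.shape[0])],
                          [f"v{j}" for j in range(d.shape[1])])


genotype_matrices = st.integers(0, 2**31 - 1).map(
    lambda s: random_genotypes(np.random.default_rng(s),
                               n=int(3 + s % 6), m=int(5 + (s >> 4) % 40)))


class TestScgrm:
    def test_two_samples_single_snp_known_variance(self):
        g = _geno([[0], [2]])
        cfg = EstimatorConfig(variance_mode="known",
                              known_variances=np.array([0.5]))
        K = scgrm(g, cfg)
        # centered scores (-1, +1): rho = -2, phi = -1
        assert 2 * K.phi[0, 1] == pytest.approx(-2.0)
        assert K.phi[0, 1] == pytest.approx(-1.0)

    def test_any_pair_of_two_is_nonpositive(self, rng):
        # with n = 2 the centered cross-product is -((x1-x2)/2)^2
        for _ in range(10):
            g = random_genotypes(rng, 2, 20)
            cfg = EstimatorConfig(variance_mode="hwe")
            assert scgrm(g, cfg).phi[0, 1] <= 1e-12

    @pytest.mark.parametrize("mode", ["sample", "hwe", "known"])
    def test_matches_per_snp_brute_force(self, rng, mode):
        g = random_genotypes(rng, 6, 50)
        kv = (np.full(50, 0.4) if mode == "known" else None)
        cfg = EstimatorConfig(variance_mode=mode, known_variances=kv)
        K = scgrm(g, cfg)
        # brute force: double loop over pairs and SNPs
        X = g.dosages.astype(float)
        mu = X.mean(axis=0)
        if mode == "sample":
            var = X.var(axis=0, ddof=1)
        elif mode == "hwe":
            p = mu / 2
            var = 2 * p * (1 - p)
        else:
            var = kv
        keep = X.var(axis=0, ddof=1) > 0 if mode != "known" else np.ones(50, bool)
        brute = np.zeros((6, 6))
        for a in range(6):
            for b in range(6):
                vals = [(X[a, j] - mu[j]) * (X[b, j] - mu[j]) / var[j]
                        for j in range(50) if keep[j]]
                brute[a, b] = np.mean(vals)
        np.testing.assert_allclose(2 * K.phi, brute, atol=1e-12)

    def test_forced_all_pairs_sum(self, geno_factory):
        # sample-variance mode with full centering: sum over pairs of
        # rho_hat is exactly -(n-1)/2 whatever the data
        g = geno_factory(n=9, m=30)
        K = scgrm(g, EstimatorConfig(variance_mode="sample"))
        i, j = np.triu_indices(9, k=1)
        total = (2 * K.phi)[i, j].sum()
        assert total == pytest.approx(-(9 - 1) / 2, abs=1e-9)

    def test_all_monomorphic_is_an_error(self):
        g = _geno([[2, 0], [2, 0], [2, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            scgrm(g, EstimatorConfig(variance_mode="sample"))


class TestRgrm:
    def test_equal_variances_collapse_to_scgrm(self):
        g = _geno([[0, 2], [2, 0], [1, 1], [0, 0], [2, 2], [1, 0]])
        kv = np.full(2, 0.37)
        cfg = EstimatorConfig(variance_mode="known", known_variances=kv)
        np.testing.assert_allclose(rgrm(g, cfg).phi, scgrm(g, cfg).phi,
                                   atol=1e-12)

    def test_matches_weighted_brute_force(self, rng):
        g = random_genotypes(rng, 6, 50)
        cfg = EstimatorConfig(variance_mode="sample")
        K = rgrm(g, cfg)
        X = g.dosages.astype(float)
        mu = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
        keep = var > 0
        brute = np.zeros((6, 6))
        for a in range(6):
            for b in range(6):
                num = sum((X[a, j] - mu[j]) * (X[b, j] - mu[j])
                          for j in range(50) if keep[j])
                brute[a, b] = num / var[keep].sum()
        np.testing.assert_allclose(2 * K.phi, brute, atol=1e-12)


class TestUkin:
    def test_two_sample_collapse(self):
        g = _geno([[0, 1, 2], [2, 1, 0], [1, 0, 1]])
        K = scgrm(g, EstimatorConfig(variance_mode="hwe"))
        Kt = ukin(K)
        rho = 2 * K.phi
        # n = 3: rho_tilde_01 = rho_01 + (rho_01+rho_02+rho_01+rho_12)/2 + 1
        expect = rho[0, 1] + 0.5 * (rho[0, 1] + rho[0, 2]) \
            + 0.5 * (rho[0, 1] + rho[1, 2]) + 1
        assert 2 * Kt.phi[0, 1] == pytest.approx(expect)

    def test_n2_reduces_to_affine_map(self, rng):
        g = random_genotypes(rng, 2, 30)
        K = scgrm(g, EstimatorConfig(variance_mode="hwe"))
        Kt = ukin(K)
        assert 2 * Kt.phi[0, 1] == pytest.approx(2 * (2 * K.phi[0, 1]) + 1)

    def test_requires_scgrm_input(self, rng):
        g = random_genotypes(rng, 4, 20)
        K = rgrm(g, EstimatorConfig(variance_mode="sample"))
        with pytest.raises(ValueError, match="scGRM"):
            ukin(K)

    @settings(max_examples=25, deadline=None)
    @given(genotype_matrices)
    def test_matrix_path_equals_per_snp_path(self, g):
        cfg = EstimatorConfig(variance_mode="sample")
        via_matrix = ukin(scgrm(g, cfg))
        direct = ukin_per_snp(g, cfg)
        np.testing.assert_allclose(via_matrix.phi, direct.phi, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_pair_average_identity(self, seed, n):
        # mean(rho_tilde) = n * mean(rho_hat) + 1 for ANY symmetric input
        rng = np.random.default_rng(seed)
        rho = rng.normal(size=(n, n))
        rho = (rho + rho.T) / 2
        K = KinshipMatrix(rho / 2, "scgrm", [f"s{i}" for i in range(n)])
        Kt = ukin(K)
        i, j = np.triu_indices(n, k=1)
        lhs = (2 * Kt.phi)[i, j].mean()
        rhs = n * (2 * K.phi)[i, j].mean() + 1
        assert lhs == pytest.approx(rhs, abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(genotype_matrices)
    def test_sample_variance_forces_zero_mean(self, g):
        # forced sum => all-pairs mean of rho_tilde is exactly 0
        Kt = ukin(scgrm(g, EstimatorConfig(variance_mode="sample")))
        i, j = np.triu_indices(g.n_samples, k=1)
        assert (2 * Kt.phi)[i, j].mean() == pytest.approx(0.0, abs=1e-9)

    def test_identical_rows_give_exact_half(self):
        # MZ-like pair: the correction cancels the diagonal exactly
        g = _geno([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 1, 2]])
        Kt = ukin(scgrm(g, EstimatorConfig(variance_mode="sample")))
        assert Kt.phi[0, 1] == pytest.approx(0.5, abs=1e-12)


class TestPermutationEquivariance:
    def test_relabeling_permutes_all_estimators(self, rng):
        g = random_genotypes(rng, 7, 60)
        perm = np.random.default_rng(1).permutation(7)
        gp = g.subset(samples=perm)
        cfg = EstimatorConfig(variance_mode="sample")
        for est in (lambda x: scgrm(x, cfg), lambda x: rgrm(x, cfg),
                    lambda x: ukin(scgrm(x, cfg)), king_robust):
            K = est(g).phi
            Kp = est(gp).phi
            np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)


class TestKing:
    def test_identical_genotypes_give_half(self):
        g = _geno([[0, 1, 2, 1], [0, 1, 2, 1]])
        assert king_robust(g).phi[0, 1] == pytest.approx(0.5)

    def test_hand_counted_example(self):
        g = _geno([[0, 1, 1, 2], [2, 1, 0, 1]])
        # N_AaAa=1, N_AAaa=1, het counts 2 and 2 -> (1-2)/4
        assert king_robust(g).phi[0, 1] == pytest.approx(-0.25)

    def test_no_heterozygotes_flagged_undefined(self):
        g = _geno([[0, 2, 0], [2, 0, 0], [1, 1, 1]])
        K = king_robust(g)
        assert np.isnan(K.phi[0, 1])
        assert ("s0", "s1") in K.meta["undefined_pairs"]

    def test_pairwise_complete_with_missing(self):
        d = [[0, 1, 1, 2, 1], [2, 1, 0, 1, 0]]
        mask = [[False, False, False, False, True],
                [False, False, True, False, False]]
        g = _geno(d, mask)
        # shared observed SNPs: 0,1,3 -> N_AaAa=1, N_AAaa=1, hets 1 and 2
        assert king_robust(g).phi[0, 1] == pytest.approx((1 - 2) / 3)

    def test_missing_path_agrees_with_loop_oracle(self, rng):
        g = random_genotypes(rng, 6, 80, missing_rate=0.1)
        K = king_robust(g)
        X = g.dosage_float()
        for a in range(6):
            for b in range(a + 1, 6):
                shared = ~np.isnan(X[a]) & ~np.isnan(X[b])
                xa, xb = X[a, shared], X[b, shared]
                num = np.sum((xa == 1) & (xb == 1)) - 2 * np.sum(
                    np.abs(xa - xb) == 2)
                den = np.sum(xa == 1) + np.sum(xb == 1)
                expect = num / den if den else np.nan
                if np.isnan(expect):
                    assert np.isnan(K.phi[a, b])
                else:
                    assert K.phi[a, b] == pytest.approx(expect)

    def test_parent_offspring_mean_quarter(self):
        from ukin import PedigreeSpec, drop_pedigree
        rng = np.random.default_rng(123)
        vals = []
        # 60 parent-offspring pairs at m=10000 (gene-dropping Monte-Carlo)
        for _ in range(60):
            spec = PedigreeSpec(founders=2, matings=[(0, 1, 1)],
                                emit=[0, 2])
            g, _ = drop_pedigree(spec, 10_000, seed=rng)
            vals.append(king_robust(g).phi[0, 1])
        assert np.mean(vals) == pytest.approx(0.25, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize("phi,degree", [
        (0.5, "MZ"), (0.4, "MZ"),
        (0.25, "first_degree"), (2 ** -1.5, "first_degree"),
        (0.125, "second_degree"), (2 ** -2.5, "second_degree"),
        (0.0625, "third_degree"), (2 ** -3.5, "third_degree"),
        (0.03, "unrelated"), (2 ** -4.5, "unrelated"), (-0.1, "unrelated"),
    ])
    def test_interval_assignment(self, phi, degree):
        assert classify_relationship(phi).degree == degree

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_relationship(float("nan"))


class TestIO:
    def test_square_matrix_round_trip(self, tmp_path, rng):
        g = random_genotypes(rng, 5, 30)
        K = ukin(scgrm(g, EstimatorConfig(variance_mode="sample")))
        write_kinship_matrix(K, tmp_path / "k.tsv")
        K2 = read_kinship_matrix(tmp_path / "k.tsv")
        np.testing.assert_allclose(K2.phi, K.phi, atol=1e-12)
        assert K2.estimator == "ukin"
        assert K2.sample_ids == K.sample_ids

    def test_grm_text_round_trip(self, tmp_path, rng):
        g = random_genotypes(rng, 5, 30)
        K = scgrm(g, EstimatorConfig(variance_mode="sample"))
        write_grm_text(K, tmp_path / "k")
        K2 = read_grm_text(tmp_path / "k", estimator="scgrm")
        np.testing.assert_allclose(K2.phi, K.phi, atol=1e-9)
        assert K2.n_snps == K.n_snps
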