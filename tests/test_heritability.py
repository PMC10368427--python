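"""GRM/GREML/twin AE correctness, pruning, and multiple-testing."""

import numpy as np
import pytest

from cortasym.heritability import (
    GRM,
    HeritabilityError,
    adjust_phenotype,
    bh_fdr,
    bonferroni_alpha,
    compute_grm,
    greml,
    greml_bivariate,
    prune_related,
    twin_ae,
    twin_ae_bivariate,
)
from cortasym.simulate import (
    FamilyData,
    GenotypePanel,
    simulate_families,
    simulate_genotype_phenotypes,
)
import pandas as pd


class TestGRM:
    def test_single_snp_hand_computed_entry(self):
        # dosages (2, 0): sample p = 0.5; diagonal for the '2' subject is
        # (2 - 1)^2 / (2 * 0.5 * 0.5) = 2.0
        panel = GenotypePanel(
            dosage=np.array([[2.0], [0.0]]), allele_freq=np.array([0.5])
        )
        grm = compute_grm(panel, maf_min=0.01)
        assert grm.matrix[0, 0] == pytest.approx(2.0)
        assert grm.matrix[1, 1] == pytest.approx(2.0)
        assert grm.matrix[0, 1] == pytest.approx(-2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.5, 50)
        dosage = rng.binomial(2, p, size=(20, 50)).astype(float)
        panel = GenotypePanel(dosage=dosage, allele_freq=p)
        grm = compute_grm(panel, maf_min=0.0)
        phat = dosage.mean(axis=0) / 2
        keep = np.minimum(phat, 1 - phat) >= 0.0
        oracle = np.zeros((20, 20))
        m = keep.sum()
        for j in range(20):
            for k in range(20):
                acc = 0.0
                for i in np.flatnonzero(keep):
                    w = 2 * phat[i] * (1 - phat[i])
                    acc += (
                        (dosage[j, i] - 2 * phat[i])
                        * (dosage[k, i] - 2 * phat[i])
                        / w
                    )
                oracle[j, k] = acc / m
        np.testing.assert_allclose(grm.matrix, oracle, atol=1e-12)

    def test_maf_filter_removes_rare_snps(self):
        dosage = np.array([[2.0, 2.0], [0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        # SNP 2 is monomorphic (p=1): must be filtered
        panel = GenotypePanel(dosage=dosage, allele_freq=np.array([0.25, 1.0]))
        grm = compute_grm(panel, maf_min=0.01)
        assert grm.n_snps == 1

    def test_unrelated_panel_diagonal_near_one(self):
        panel, _, _ = simulate_genotype_phenotypes(
            n_subjects=500, n_snps=2000, h2=0.0, seed=1
        )
        grm = compute_grm(panel)
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.05
        off = grm.matrix[np.triu_indices(500, 1)]
        assert abs(off.mean()) < 0.01

    def test_duplicated_individual_detected(self):
        panel, _, truth = simulate_genotype_phenotypes(
            n_subjects=100, n_snps=1000, related_pairs=2, seed=2
        )
        grm = compute_grm(panel)
        for i, j in truth.extras["related_pairs"]:
            assert grm.matrix[i, j] > 0.9

    def test_missing_dosages_mean_imputed(self):
        panel, _, _ = simulate_genotype_phenotypes(
            n_subjects=200, n_snps=500, missing_rate=0.05, seed=3
        )
        grm = compute_grm(panel)
        assert np.all(np.isfinite(grm.matrix))
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.1


class TestPruning:
    @staticmethod
    def _grm_with_pairs(n, pairs, value=0.5):
        m = np.eye(n)
        for i, j in pairs:
            m[i, j] = m[j, i] = value
        return GRM(matrix=m, n_snps=100)

    def test_one_of_each_pair_removed(self):
        grm = self._grm_with_pairs(10, [(0, 1), (4, 7)])
        kept = prune_related(grm, cutoff=0.025)
        assert len(kept) == 8
        assert (0 in kept) != (1 in kept)
        assert (4 in kept) != (7 in kept)

    def test_no_related_pairs_keeps_everyone(self):
        grm = self._grm_with_pairs(10, [])
        np.testing.assert_array_equal(prune_related(grm), np.arange(10))

    def test_three_clique_keeps_one(self):
        grm = self._grm_with_pairs(6, [(0, 1), (0, 2), (1, 2)])
        kept = prune_related(grm)
        assert len(kept) == 4
        assert len({0, 1, 2} & set(kept)) == 1

    def test_idempotent_on_pruned_set(self):
        grm = self._grm_with_pairs(12, [(0, 1), (2, 3), (2, 4)])
        kept = prune_related(grm)
        sub = grm.subset(kept)
        np.testing.assert_array_equal(
            prune_related(sub), np.arange(len(kept))
        )


@pytest.fixture(scope="module")
def planted_half():
    panel, y, _ = simulate_genotype_phenotypes(
        n_subjects=1000, n_snps=2000, h2=0.5, seed=5
    )
    grm = compute_grm(panel)
    return y, grm


class TestGreml:
    def test_recovers_planted_h2_within_two_se(self, planted_half):
        y, grm = planted_half
        est = greml(y, grm)
        assert abs(est.h2 - 0.5) <= 2 * est.se
        assert est.p < 0.01
        assert est.converged

    def test_variance_components_sum_to_phenotypic_variance(self, planted_half):
        y, grm = planted_half
        est = greml(y, grm)
        total = est.var_genetic + est.var_env
        assert abs(total - y.var()) / y.var() < 0.10

    def test_null_heritability_small_and_calibrated(self):
        panel, _, _ = simulate_genotype_phenotypes(
            n_subjects=500, n_snps=1500, h2=0.0, seed=6
        )
        grm = compute_grm(panel)
        grm.eig()
        rng = np.random.default_rng(7)
        h2s, ps = [], []
        for _ in range(10):
            est = greml(rng.standard_normal(500), grm)
            h2s.append(est.h2)
            ps.append(est.p)
        assert np.mean(h2s) <= 0.08
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2

    def test_subject_permutation_leaves_h2_unchanged(self, planted_half):
        y, grm = planted_half
        est = greml(y, grm)
        perm = np.random.default_rng(8).permutation(len(y))
        est_p = greml(y[perm], GRM(grm.matrix[np.ix_(perm, perm)],
                                   grm.n_snps))
        assert abs(est.h2 - est_p.h2) < 1e-8

    def test_loglik_trace_is_ascending(self, planted_half):
        y, grm = planted_half
        est = greml(y, grm)
        assert est.loglik >= est.null_loglik - 1e-9


class TestGremlBivariate:
    def test_identical_traits_hit_unit_genetic_correlation(self):
        panel, y, _ = simulate_genotype_phenotypes(
            n_subjects=400, n_snps=1000, h2=0.5, seed=9
        )
        grm = compute_grm(panel)
        est = greml_bivariate(y, y.copy(), grm)
        assert est.rG > 0.98

    def test_recovers_planted_genetic_correlation(self):
        from cortasym.simulate import simulate_bivariate_phenotypes

        panel, _, _ = simulate_genotype_phenotypes(
            n_subjects=800, n_snps=2000, h2=0.5, seed=10
        )
        grm = compute_grm(panel)
        y1, y2, _ = simulate_bivariate_phenotypes(panel, rG=0.6, seed=11)
        est = greml_bivariate(y1, y2, grm)
        se = est.se if np.isfinite(est.se) and est.se > 0 else 0.15
        assert abs(est.rG - 0.6) <= max(2 * se, 0.2)
        assert est.p < 0.05


class TestTwinAE:
    @staticmethod
    def _moment_exact_families(n_pairs=200):
        """Pairs whose ML sample moments are exactly (1, .5) MZ / (1, .25) DZ."""
        rng = np.random.default_rng(12)
        rows = []
        fam = 0
        for rel, r in (("MZ", 0.5), ("DZ", 0.25)):
            z = rng.standard_normal((n_pairs, 2))
            z = z - z.mean(axis=0)
            cov = (z.T @ z) / n_pairs
            w, q = np.linalg.eigh(cov)
            white = z @ q @ np.diag(1 / np.sqrt(w)) @ q.T
            target = np.array([[1.0, r], [r, 1.0]])
            y = white @ np.linalg.cholesky(target).T
            for k in range(n_pairs):
                for j in range(2):
                    rows.append(
                        {
                            "family_id": f"{rel}{fam + k}",
                            "member_id": f"{rel}{fam + k}m{j}",
                            "relation_class": rel,
                            "age": 30.0,
                            "sex": 0,
                            "y1": y[k, j],
                        }
                    )
            fam += n_pairs
        return FamilyData(table=pd.DataFrame(rows))

    def test_closed_form_on_moment_exact_data(self):
        # empirical cov_MZ = 0.5, cov_DZ = 0.25 = cov_MZ / 2 and unit
        # variances: the AE likelihood is maximized exactly at a2 = e2 = 0.5
        fam = self._moment_exact_families()
        est = twin_ae(fam, adjust=False)
        assert est.var_genetic == pytest.approx(0.5, abs=1e-3)
        assert est.var_env == pytest.approx(0.5, abs=1e-3)
        assert est.h2 == pytest.approx(0.5, abs=1e-3)

    def test_null_genetics_at_boundary(self):
        fam, _ = simulate_families(n_mz=300, n_dz=300, a2=0.0, e2=1.0,
                                   seed=13)
        est = twin_ae(fam)
        assert est.var_genetic <= 0.05
        assert est.p > 0.01

    def test_recovery_within_tolerance(self):
        fam, _ = simulate_families(n_mz=500, n_dz=500, a2=0.5, e2=0.5,
                                   seed=14)
        est = twin_ae(fam)
        assert abs(est.var_genetic - 0.5) <= 0.1
        assert est.p < 1e-6

    def test_trio_families_supported(self):
        fam, _ = simulate_families(n_mz=200, n_dz=200, n_trio_mz=100,
                                   a2=0.5, e2=0.5, seed=15)
        est = twin_ae(fam)
        assert abs(est.var_genetic - 0.5) <= 0.15

    def test_single_relationship_class_rejected(self):
        fam, _ = simulate_families(n_mz=0, n_dz=100, a2=0.5, e2=0.5, seed=16)
        with pytest.raises(HeritabilityError):
            twin_ae(fam)


class TestTwinBivariate:
    def test_unit_rg_with_equal_a2_hits_constraint(self):
        fam, _ = simulate_families(n_mz=500, n_dz=500, a2=0.5, e2=0.5,
                                   rG=1.0, seed=17)
        est = twin_ae_bivariate(fam)
        assert est.rG >= 0.95

    def test_independent_genetics_near_zero(self):
        fam, _ = simulate_families(n_mz=500, n_dz=500, a2=0.5, e2=0.5,
                                   rG=0.0, seed=18)
        est = twin_ae_bivariate(fam)
        assert abs(est.rG) <= 0.15

    def test_trait_order_symmetry(self):
        fam, _ = simulate_families(n_mz=300, n_dz=300, a2=0.5, e2=0.5,
                                   rG=0.5, seed=19)
        a = twin_ae_bivariate(fam, traits=("y1", "y2"))
        b = twin_ae_bivariate(fam, traits=("y2", "y1"))
        assert a.rG == pytest.approx(b.rG, abs=1e-3)


class TestMultipleTesting:
    def test_worked_four_value_example_rejects_all(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = bh_fdr([0.04], q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_matches_definitional_brute_force(self):
        rng = np.random.default_rng(20)

        def brute(p, q):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            ps = p[order]
            below = np.flatnonzero(ps <= (np.arange(1, m + 1) * q / m))
            k = below.max() + 1 if below.size else 0
            reject = np.zeros(m, bool)
            reject[order[:k]] = True
            return reject

        for _ in range(200):
            p = rng.random(500) ** rng.uniform(0.5, 3)
            ours, _ = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(ours, brute(p, 0.05))

    def test_invalid_p_rejected(self):
        with pytest.raises(HeritabilityError):
            bh_fdr([0.5, 1.2])

    def test_bonferroni_helper(self):
        assert bonferroni_alpha(20, 0.05) == pytest.approx(0.0025)


def test_adjust_phenotype_orthogonal_and_standardized():
    rng = np.random.default_rng(21)
    age = rng.uniform(20, 80, 500)
    sex = rng.integers(0, 2, 500)
    y = 0.02 * age + 0.3 * sex + rng.standard_normal(500)
    z = adjust_phenotype(y, age, sex)
    assert abs(np.corrcoef(z, age)[0, 1]) < 1e-10
    assert z.std() == pytest.approx(1.0)
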