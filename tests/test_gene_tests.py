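"""Gene-level statistics, the MVN simulation null and the adaptive ladder."""

import numpy as np
import pytest
from scipy import stats

from genewise import (GeneTestConfig, Statistic, adaptive_gene_test,
                      empirical_p, estimate_ld, make_ld_matrix,
                      observed_statistic, p_to_chisq1, regularize_ld,
                      run_gene_tests, simulate_null_statistics)
from genewise.gene_mapping import GeneSnpAssignment
from genewise.io_formats import GeneRegion, SnpAssocRecord


class TestPToChisq1:
    @pytest.mark.parametrize("p,expected", [
        (1.0, 0.0),
        (0.3173105, 1.0),    # |z| = 1
        (0.0455003, 4.0),    # |z| = 2
    ])
    def test_inverts_the_one_df_tail(self, p, expected):
        assert p_to_chisq1(p) == pytest.approx(expected, abs=1e-5)

    def test_vectorized(self):
        out = p_to_chisq1([1.0, 0.3173105])
        assert out == pytest.approx([0.0, 1.0], abs=1e-5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            p_to_chisq1(0.0)

    def test_extreme_p_clamped_finite(self):
        assert np.isfinite(p_to_chisq1(1e-320))


class TestObservedStatistic:
    def test_all_ones_sum_to_zero(self):
        assert observed_statistic([1, 1, 1], "sum_chisq") == 0.0

    def test_single_snp_reduces_to_inversion(self):
        assert observed_statistic([0.3173105], "sum_chisq") == pytest.approx(1.0, abs=1e-5)

    def test_min_p(self):
        assert observed_statistic([0.5, 0.01, 0.2], "min_p") == 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            observed_statistic([], "min_p")


class TestEstimateLd:
    def test_independent_columns_near_identity(self, rng):
        g = rng.integers(0, 3, size=(10_000, 4)).astype(float)
        ld = estimate_ld(g)
        off = ld.r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_duplicated_column_regularized(self, rng):
        col = rng.integers(0, 3, size=100).astype(float)
        ld = estimate_ld(np.column_stack([col, col]), eigen_floor=1e-8)
        assert np.linalg.eigvalsh(ld.r).min() >= 1e-8 * 0.99
        assert np.allclose(np.diag(ld.r), 1.0)

    def test_single_column(self, rng):
        ld = estimate_ld(rng.integers(0, 3, size=50).astype(float))
        assert ld.r.shape == (1, 1) and ld.r[0, 0] == 1.0

    def test_monomorphic_column_named(self):
        g = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="monomorphic.*s1"):
            estimate_ld(g)


class TestSimulateNull:
    def test_k1_matches_one_df_chisq(self):
        sims = simulate_null_statistics(make_ld_matrix(1, 0.0), 10_000,
                                        "sum_chisq", seed=5)
        ks = stats.kstest(sims, stats.chi2(df=1).cdf).statistic
        assert ks < 1.63 / np.sqrt(sims.size)

    def test_identity_sum_mean_equals_df(self):
        sims = simulate_null_statistics(make_ld_matrix(10, 0.0), 50_000,
                                        "sum_chisq", seed=5)
        assert sims.mean() == pytest.approx(10.0, abs=0.15)

    def test_perfect_ld_inflates_variance(self):
        # rho -> 1 with k = 2: replicate ~ 2 z^2, variance 8 (vs 4 independent)
        ld = regularize_ld(make_ld_matrix(2, 0.9999), 1e-8)
        sims = simulate_null_statistics(ld, 100_000, "sum_chisq", seed=5)
        assert sims.var() == pytest.approx(8.0, rel=0.1)

    def test_min_p_replicates_uniform_for_k1(self):
        sims = simulate_null_statistics(make_ld_matrix(1, 0.0), 10_000,
                                        "min_p", seed=5)
        ks = stats.kstest(sims, "uniform").statistic
        assert ks < 1.63 / np.sqrt(sims.size)

    def test_seed_determinism(self):
        ld = make_ld_matrix(3, 0.5)
        a = simulate_null_statistics(ld, 1000, "sum_chisq", seed=2)
        b = simulate_null_statistics(ld, 1000, "sum_chisq", seed=2)
        assert np.array_equal(a, b)

    def test_unregularized_degenerate_ld_errors(self):
        from genewise.synthetic_data import LdMatrix
        r = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            simulate_null_statistics(LdMatrix(r, ["a", "b"]), 10, "sum_chisq", 0)


class TestEmpiricalP:
    def test_observed_below_all_sims(self):
        assert empirical_p(0.0, np.array([1.0, 2.0, 3.0]), "sum_chisq") == (1.0, False)

    def test_zero_exceedances_reported_as_bound(self):
        p, bound = empirical_p(5000.0, np.arange(1000, dtype=float), "sum_chisq")
        assert (p, bound) == (1e-3, True)

    def test_median_gives_half(self, rng):
        nulls = rng.chisquare(1, size=100_001)
        p, _ = empirical_p(float(np.median(nulls)), nulls, "sum_chisq")
        assert p == pytest.approx(0.5, abs=0.01)

    def test_min_p_direction(self):
        nulls = np.array([0.1, 0.2, 0.3, 0.4])
        assert empirical_p(0.2, nulls, "min_p")[0] == 0.5

    def test_monotone_in_observed(self, rng):
        nulls = rng.chisquare(5, size=5000)
        grid = np.linspace(0, 20, 50)
        ps = [empirical_p(x, nulls, "sum_chisq")[0] for x in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAdaptiveLadder:
    def test_unremarkable_gene_stops_at_stage_one(self):
        cfg = GeneTestConfig(statistic="sum_chisq", seed=1)
        res = adaptive_gene_test([0.5], make_ld_matrix(1, 0.0), cfg)
        assert res.n_sims_used == 1000
        assert not res.is_upper_bound

    def test_moderate_gene_stops_at_stage_two(self):
        # true p ~ 0.004: below the 0.1 stage-1 gate, above the 0.001 stage-2 gate
        cfg = GeneTestConfig(statistic="sum_chisq", seed=1)
        res = adaptive_gene_test([0.004], make_ld_matrix(1, 0.0), cfg)
        assert res.n_sims_used == 10_000
        assert res.empirical_p == pytest.approx(0.004, abs=0.003)

    def test_single_snp_empirical_p_matches_snp_p(self):
        cfg = GeneTestConfig(statistic="sum_chisq", seed=4)
        res = adaptive_gene_test([0.5], make_ld_matrix(1, 0.0), cfg)
        assert abs(res.empirical_p - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_min_p_single_snp_reproduces_snp_p(self):
        cfg = GeneTestConfig(statistic="min_p", seed=4)
        res = adaptive_gene_test([0.3], make_ld_matrix(1, 0.0), cfg)
        assert res.empirical_p == pytest.approx(0.3, abs=3 * np.sqrt(0.21 / 10_000))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            adaptive_gene_test([0.5, 0.5], make_ld_matrix(1, 0.0), GeneTestConfig())


class TestRunGeneTests:
    @staticmethod
    def _toy():
        assoc = [SnpAssocRecord("s1", "1", 100, 0.4),
                 SnpAssocRecord("s2", "1", 200, 0.9),
                 SnpAssocRecord("s3", "1", 5_000_000, 0.2)]
        genes = [GeneRegion("A", "1", 50, 250), GeneRegion("B", "1", 4_999_000, 5_001_000),
                 GeneRegion("EMPTY", "2", 1, 10)]
        assignments = [GeneSnpAssignment(genes[0], [0, 1]),
                       GeneSnpAssignment(genes[1], [2]),
                       GeneSnpAssignment(genes[2], [])]
        lds = {"A": make_ld_matrix(2, 0.3), "B": make_ld_matrix(1, 0.0)}
        return assoc, assignments, lds

    def test_empty_assignments_give_empty_results(self):
        assert run_gene_tests([], [], {}, GeneTestConfig()) == []

    def test_genes_without_snps_skipped(self):
        assoc, assignments, lds = self._toy()
        results = run_gene_tests(assoc, assignments, lds, GeneTestConfig(seed=7))
        assert [r.gene for r in results] == ["A", "B"]

    def test_missing_ld_names_gene(self):
        assoc, assignments, _ = self._toy()
        with pytest.raises(KeyError, match="'B'"):
            run_gene_tests(assoc, assignments, {"A": make_ld_matrix(2, 0.3)},
                           GeneTestConfig(seed=7))

    def test_seeded_determinism(self):
        assoc, assignments, lds = self._toy()
        r1 = run_gene_tests(assoc, assignments, lds, GeneTestConfig(seed=7))
        r2 = run_gene_tests(assoc, assignments, lds, GeneTestConfig(seed=7))
        assert r1 == r2
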