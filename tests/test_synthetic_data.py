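"""Synthetic study generator: LD construction, MVN summaries, genotypes."""

import numpy as np
import pytest
from scipy import stats

from genewise import (SimulationConfig, allelic_test, allelic_test_p,
                      generate_study, make_ld_matrix, simulate_genotypes,
                      simulate_summary_z)


class TestMakeLdMatrix:
    def test_rho_zero_is_identity(self):
        assert np.array_equal(make_ld_matrix(3, 0.0).r, np.eye(3))

    def test_ar1_off_diagonal(self):
        r = make_ld_matrix(2, 0.5).r
        assert r[0, 1] == r[1, 0] == 0.5

    def test_strong_ld_stays_positive_definite(self):
        vals = np.linalg.eigvalsh(make_ld_matrix(50, 0.9).r)
        assert vals.min() > 0

    @pytest.mark.parametrize("k,rho", [(0, 0.5), (3, 1.0), (3, -0.1)])
    def test_invalid_parameters(self, k, rho):
        with pytest.raises(ValueError):
            make_ld_matrix(k, rho)


class TestSimulateSummaryZ:
    def test_null_pvalues_uniform(self):
        ld = make_ld_matrix(1, 0.0)
        draws = np.array([simulate_summary_z(ld, [0.0], s)[1][0]
                          for s in range(10_000)])
        ks = stats.kstest(draws, "uniform").statistic
        assert ks < 1.63 / np.sqrt(draws.size)  # 1% critical value

    def test_marginal_variance_is_one(self, rng):
        ld = make_ld_matrix(4, 0.6)
        z = np.array([simulate_summary_z(ld, np.zeros(4), rng)[0]
                      for _ in range(10_000)])
        assert np.allclose(z.var(axis=0), 1.0, atol=0.06)

    def test_noncentral_snp_has_tiny_p(self):
        ld = make_ld_matrix(3, 0.2)
        mu = np.array([0.0, 5.0, 0.0])
        ps = np.array([simulate_summary_z(ld, mu, s)[1][1] for s in range(1_000)])
        assert np.median(ps) < 1e-4

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            simulate_summary_z(make_ld_matrix(3, 0.0), [0.0, 0.0], 0)


class TestSimulateGenotypes:
    def test_mean_dosage_at_half_maf(self):
        ld = make_ld_matrix(2, 0.0)
        g = simulate_genotypes(ld, [0.5, 0.5], 10_000, 7)
        assert np.allclose(g.mean(axis=0), 1.0, atol=0.05)

    def test_rare_allele_mostly_zero(self):
        g = simulate_genotypes(make_ld_matrix(1, 0.0), [0.005], 500, 7)
        assert (g == 0).mean() > 0.95

    def test_seed_determinism(self):
        ld = make_ld_matrix(5, 0.5)
        a = simulate_genotypes(ld, [0.3] * 5, 50, 11)
        b = simulate_genotypes(ld, [0.3] * 5, 50, 11)
        assert np.array_equal(a, b)

    def test_maf_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_genotypes(make_ld_matrix(1, 0.0), [0.7], 10, 0)


class TestAllelicTest:
    def test_two_by_two_worked_example(self):
        # allele table cases 30/170, controls 20/180:
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 2.2857..., 1-df tail 0.1306
        cases = [1] * 30 + [0] * 70       # 100 cases -> 200 alleles, 30 minor
        controls = [1] * 20 + [0] * 80
        stat, p, mono = allelic_test(cases, controls)
        assert not mono
        assert stat == pytest.approx(2.2857, abs=1e-4)
        assert p == pytest.approx(0.1306, abs=1e-4)

    def test_null_large_sample_p_near_one(self):
        cases = [1, 0] * 500
        controls = [1, 0] * 500
        assert allelic_test_p(cases, controls) == pytest.approx(1.0)

    def test_monomorphic_flagged(self):
        stat, p, mono = allelic_test([0, 0], [0, 0])
        assert (stat, p, mono) == (0.0, 1.0, True)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allelic_test([], [1])


class TestGenerateStudy:
    def test_default_bookkeeping(self, default_study):
        cfg, paths = default_study
        lines = paths.assoc.read_text().splitlines()
        assert len(lines) - 1 == cfg.n_genes * cfg.snps_per_gene == 1000
        glist = paths.glist.read_text().splitlines()
        assert len(glist) == cfg.n_genes

    def test_truth_all_null_without_causal_genes(self, tmp_path):
        cfg = SimulationConfig(n_genes=6, snps_per_gene=3, causal_genes=(),
                               write_reference_panel=False, seed=3)
        paths = generate_study(cfg, tmp_path)
        flags = [line.split("\t")[1] for line in
                 paths.truth.read_text().splitlines()[1:]]
        assert set(flags) == {"0"}

    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_genes=5, snps_per_gene=4, seed=9,
                               causal_genes=("G001",), n_reference=30)
        p1 = generate_study(cfg, tmp_path / "a")
        p2 = generate_study(cfg, tmp_path / "b")
        for name in ("assoc", "glist", "gmt", "truth", "reference_panel"):
            assert getattr(p1, name).read_bytes() == getattr(p2, name).read_bytes()

    def test_gmt_contains_planted_and_edge_case_pathways(self, default_study):
        from genewise.io_formats import read_gmt
        _cfg, paths = default_study
        ids = {s[0] for s in read_gmt(paths.gmt)}
        assert {"PW_CAUSAL", "PW_DECOY19", "PW_DECOY20",
                "PW_DECOY300", "PW_DECOY301"} <= ids

    def test_intergene_gaps_exceed_twice_flank(self, default_study):
        from genewise.io_formats import read_gene_ranges
        _cfg, paths = default_study
        regions = read_gene_ranges(paths.glist)
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end > 100_000

    def test_causal_genes_must_exist(self):
        with pytest.raises(ValueError, match="causal"):
            SimulationConfig(n_genes=2, causal_genes=("G999",))
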