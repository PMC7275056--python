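"""Simulation harness: haplotype pool, genotypes, phenotypes, studies."""

import numpy as np
import pytest

from mtar.simulate import (NULL_CONFIG, EffectConfig, PhenotypeModel,
                           StudyDesign, design_zeta,
                           generate_cohort_genotypes, generate_haplotype_pool,
                           generate_phenotypes, run_study)
from mtar.trait_cov import OverlapCounts, zeta_analytic, zeta_empirical
import pandas as pd


class TestHaplotypePool:
    def test_deterministic_given_seed(self):
        p1 = generate_haplotype_pool(n_sites=500, seed=42)
        p2 = generate_haplotype_pool(n_sites=500, seed=42)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(p1.positions, p2.positions)

    def test_pool_mafs_within_rare_truncation(self):
        pool = generate_haplotype_pool(n_sites=1000, seed=1)
        assert np.all(pool.maf > 0.0)
        assert np.all(pool.maf <= 0.05)

    def test_sfs_shape_singletons_exceed_doubletons(self):
        pool = generate_haplotype_pool(n_sites=10**4, seed=2)
        counts = pool.haplotypes.sum(axis=0)
        assert np.sum(counts == 1) > np.sum(counts == 2)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            generate_haplotype_pool(n_sites=1, seed=0)


class TestCohortGenotypes:
    def test_identical_haplotypes_give_identical_genotypes(self, rng):
        pool = generate_haplotype_pool(n_sites=200, seed=3)
        pool.haplotypes[:] = pool.haplotypes[0]
        design = StudyDesign(cohort_sizes=(30,), availability=[[1]],
                             m_variants=None)
        # a constant pool is monomorphic in the sample: no usable window
        with pytest.raises(RuntimeError):
            generate_cohort_genotypes(pool, design, rng, max_retries=5)

    def test_genotype_values_and_maf_cap(self, rng):
        pool = generate_haplotype_pool(n_sites=2000, seed=4)
        design = StudyDesign(cohort_sizes=(200, 100),
                             availability=[[1], [1]], m_variants=None)
        region = generate_cohort_genotypes(pool, design, rng)
        g = np.vstack(region.genotypes)
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}
        assert np.all(region.maf > 0) and np.all(region.maf < 0.05)

    def test_sample_mafs_track_pool_mafs(self, rng):
        pool = generate_haplotype_pool(n_sites=2000, seed=5)
        design = StudyDesign(cohort_sizes=(8500,), availability=[[1]],
                             m_variants=None)
        region = generate_cohort_genotypes(pool, design, rng)
        pos_to_maf = dict(zip(pool.positions, pool.maf))
        pool_maf = np.array([pos_to_maf[p] for p in
                             region.variants["pos"]])
        n = 2 * 8500
        se = np.sqrt(pool_maf * (1 - pool_maf) / n)
        assert np.all(np.abs(region.maf - pool_maf) < 3 * se + 1e-9)


class TestPhenotypes:
    def test_residual_correlation_recovered(self, rng):
        model = PhenotypeModel(covariate_effects=(0.0, 0.0))
        pool = generate_haplotype_pool(n_sites=2000, seed=6)
        design = StudyDesign(cohort_sizes=(8500,),
                             availability=[[1, 1, 1]], m_variants=5)
        region = generate_cohort_genotypes(pool, design, rng)
        beta = np.zeros((3, region.maf.size))
        pheno = generate_phenotypes(region, design, beta, model, rng)
        got = np.corrcoef(pheno[0]["Y"], rowvar=False)
        assert np.allclose(got, model.residual_cov, atol=0.03)

    def test_unavailable_traits_are_nan(self, rng):
        model = PhenotypeModel()
        pool = generate_haplotype_pool(n_sites=2000, seed=7)
        design = StudyDesign(cohort_sizes=(50, 40),
                             availability=[[1, 1, 0], [0, 0, 1]],
                             m_variants=None)
        region = generate_cohort_genotypes(pool, design, rng)
        pheno = generate_phenotypes(region, design,
                                    np.zeros((3, region.maf.size)),
                                    model, rng)
        assert np.all(np.isnan(pheno[0]["Y"][:, 2]))
        assert np.all(np.isnan(pheno[1]["Y"][:, :2]))
        assert np.all(np.isfinite(pheno[1]["Y"][:, 2]))


class TestEffectConfig:
    def test_effect_magnitude_scales_with_log_maf(self, rng):
        cfg = EffectConfig(d=0.3, causal_fraction=1.0,
                           trait_pattern=(0, 0, 1))
        beta = cfg.draw_beta(np.array([0.001, 0.01]), rng)
        assert np.all(beta[:2] == 0.0)
        assert abs(beta[2, 0]) / abs(beta[2, 1]) == pytest.approx(1.5)
        assert beta[2, 0] == pytest.approx(0.3 * 3.0)

    def test_null_config_all_zero(self, rng):
        assert np.all(NULL_CONFIG.draw_beta(np.array([0.01] * 4), rng) == 0)

    def test_random_signs_mix(self):
        rng = np.random.default_rng(0)
        cfg = EffectConfig(d=0.2, causal_fraction=1.0,
                           trait_pattern=(1,), snp_sign="random")
        beta = cfg.draw_beta(np.full(50, 0.01), rng)
        assert np.any(beta > 0) and np.any(beta < 0)

    def test_trait_pattern_signs(self, rng):
        cfg = EffectConfig(d=0.2, causal_fraction=1.0,
                           trait_pattern=(1, -1, 1))
        beta = cfg.draw_beta(np.full(6, 0.01), rng)
        assert np.all(beta[0] == -beta[1])
        assert np.all(beta[0] == beta[2])


class TestDesignZeta:
    def test_default_three_cohort_values(self):
        design = StudyDesign()
        model = PhenotypeModel()
        zeta = design_zeta(design, model).zeta
        # trait 1 and 2 share cohorts 1+2 completely: zeta = cor = 0.1
        assert zeta[0, 1] == pytest.approx(6500 / 6500 * 0.1)
        # traits 1 and 3 share cohort 1 only, residual cor 0
        assert zeta[0, 2] == pytest.approx(0.0)
        # traits 2 and 3 share cohort 1, cor -0.1
        assert zeta[1, 2] == pytest.approx(3000 * -0.1 /
                                           np.sqrt(6500 * 5000))

    def test_overlap_counts_match_definition(self):
        design = StudyDesign()
        c = design.overlap_counts(0, 2, cor=0.5)
        assert (c.n_a, c.n_b, c.n_c) == (6500, 5000, 3000)


class TestRunStudy:
    def test_deterministic_given_seed(self):
        design = StudyDesign(cohort_sizes=(300, 200, 150), m_variants=6)
        t1 = run_study(design, [NULL_CONFIG], alpha=0.05, n_replicates=100,
                       seed=9, n_regions=4)
        t2 = run_study(design, [NULL_CONFIG], alpha=0.05, n_replicates=100,
                       seed=9, n_regions=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_calibration_loose(self):
        design = StudyDesign(cohort_sizes=(400, 300, 200), m_variants=6)
        tab = run_study(design, [NULL_CONFIG], alpha=0.05,
                        n_replicates=600, seed=10, n_regions=6)
        se = np.sqrt(0.05 * 0.95 / 600)
        for _, row in tab.iterrows():
            assert abs(row["rate"] - 0.05) < 4 * se, row["test"]

    def test_power_increases_with_effect_size(self):
        design = StudyDesign(cohort_sizes=(400, 300, 200), m_variants=6)
        rates = []
        for d in (0.0, 0.6):
            cfg = EffectConfig(d=d, causal_fraction=0.5,
                               trait_pattern=(1, 1, 1)) if d else NULL_CONFIG
            tab = run_study(design, [cfg], alpha=0.01, n_replicates=300,
                            seed=12, n_regions=3, tests=("MTAR-O",))
            rates.append(float(tab["rate"].iloc[0]))
        assert rates[1] > rates[0] + 0.1

    def test_rejects_tiny_replicate_counts(self):
        with pytest.raises(ValueError, match="100"):
            run_study(StudyDesign(), [NULL_CONFIG], alpha=0.05,
                      n_replicates=10, seed=1)


class TestEngineEquivalence:
    def test_batched_battery_matches_per_gene_path(self, rng):
        """The stacked simulation engine reproduces mtar_gene_test P-values
        to machine precision on identical inputs."""
        from mtar._batch import battery_batch
        from mtar.gene_tests import mtar_gene_test
        from mtar.kernels import variant_weights
        from mtar.simulate import (LIPID_GENETIC_CORRELATION,
                                   _meta_score_stats)
        from mtar.sumstats import ScoreStats
        from mtar.trait_cov import joint_from_uv

        design = StudyDesign(cohort_sizes=(400, 300, 200), m_variants=6)
        model = PhenotypeModel()
        pool = generate_haplotype_pool(n_sites=2000, seed=8)
        region = generate_cohort_genotypes(pool, design, rng)
        grams = [g.T @ g for g in region.genotypes]
        zeta = design_zeta(design, model)
        C = LIPID_GENETIC_CORRELATION
        B = 5
        m = region.maf.size
        Ub = np.zeros((B, 3, m))
        Vb = np.zeros((B, 3, m, m))
        keys = {"MTAR-O": "p_mtar_o", "cMTAR": "p_cmtar",
                "iMTAR": "p_imtar", "cctP": "p_cctp", "minP": "p_minp"}
        ref = {k: [] for k in keys}
        for b in range(B):
            pheno = generate_phenotypes(region, design, np.zeros((3, m)),
                                        model, rng)
            U, V = _meta_score_stats(region, design, pheno, grams)
            Ub[b], Vb[b] = U, V
            stats_ = [ScoreStats(trait=f"trait{k+1}", gene="g",
                                 variants=region.variants, U=U[k], V=V[k],
                                 maf=region.maf, n_samples=700)
                      for k in range(3)]
            joint = joint_from_uv([s.U for s in stats_],
                                  [s.V for s in stats_], zeta.zeta,
                                  region.ld.R, traits=zeta.traits,
                                  variants=region.variants, maf=region.maf)
            res = mtar_gene_test(stats_, region.ld, zeta, C=C, acc=1e-6,
                                 joint=joint)
            for k, attr in keys.items():
                ref[k].append(getattr(res, attr))
        out = battery_batch(Ub, Vb, zeta.zeta, region.ld.R, C,
                            variant_weights(region.maf), acc=1e-6)
        for k in keys:
            assert np.allclose(ref[k], out[k], atol=1e-10), k


class TestOverlapLoopClosure:
    def test_empirical_zeta_matches_analytic_on_null_variants(self, rng):
        """Score-statistic Z-scores from overlapping gaussian cohorts have
        the covariance predicted by the analytic overlap formula."""
        n_a = n_b = 1000
        n_c = 500
        target_cor = 0.3
        n_tot = n_a + n_b - n_c
        chol = np.linalg.cholesky([[1.0, target_cor], [target_cor, 1.0]])
        m = 2 * 10**4
        za = np.empty(m)
        zb = np.empty(m)
        # phenotypes are redrawn per chunk so Z-scores are independent
        # across chunks and the estimator converges to the analytic value
        for start in range(0, m, 500):
            k = min(500, m - start)
            y = rng.standard_normal((n_tot, 2)) @ chol.T
            y1 = y[:n_a, 0]
            y2 = y[n_a - n_c:, 1]
            g = rng.binomial(2, rng.uniform(0.1, 0.5, k),
                             size=(n_tot, k)).astype(float)
            for z, yk, sl in ((za, y1, slice(0, n_a)),
                              (zb, y2, slice(n_a - n_c, n_tot))):
                gs = g[sl]
                gc = gs - gs.mean(axis=0)
                resid = yk - yk.mean()
                a = np.mean(resid**2)
                u = gc.T @ resid / a
                v = (gc**2).sum(axis=0) / a
                z[start:start + k] = u / np.sqrt(v)
        tab = {
            "a": pd.DataFrame({"CHR": "1", "POS": np.arange(m) * 10**6,
                               "Z": za}),
            "b": pd.DataFrame({"CHR": "1", "POS": np.arange(m) * 10**6,
                               "Z": zb}),
        }
        est = zeta_empirical(tab).zeta[0, 1]
        expect = zeta_analytic(OverlapCounts(n_a=n_a, n_b=n_b, n_c=n_c,
                                             cor=target_cor))
        assert expect == pytest.approx(0.15)
        assert est == pytest.approx(expect, abs=3.0 / np.sqrt(m))
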