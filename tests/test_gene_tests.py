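"""Variance-component statistics, Cauchy combinations and the omnibus."""

import math

import numpy as np
import pytest
import sympy
from scipy import stats

from mtar.gene_tests import (cauchy_combine, cauchy_statistic,
                             mtar_gene_test, mtar_grid_test, omnibus,
                             q_rho_test, single_trait_tests)
from mtar.kernels import build_effect_kernel, variant_weights
from mtar.sumstats import LDMatrix, ScoreStats, default_variants
from mtar.trait_cov import JointStats, assemble_joint


def make_single_trait_fixture(seed=7, m=20, n=800):
    """Seeded one-trait gene: genotypes, scores, LD."""
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, rng.uniform(0.005, 0.04, m), size=(n, m)).astype(
        float)
    keep = g.std(axis=0) > 0
    g = g[:, keep]
    m = g.shape[1]
    y = rng.standard_normal(n) + g[:, 0] * 0.15
    variants = default_variants(m)
    resid = y - y.mean()
    a = np.mean(resid**2)
    u = g.T @ resid / a
    gc = g - g.mean(axis=0)
    v = gc.T @ gc / a
    st_ = ScoreStats(trait="t1", gene="g", variants=variants, U=u, V=v,
                     maf=g.mean(axis=0) / 2.0, n_samples=n)
    ld = LDMatrix(variants=variants, R=np.corrcoef(g, rowvar=False))
    return st_, ld


from oracles import ruben_sf


class TestQRho:
    def test_null_point(self, variants3):
        ld = LDMatrix(variants=variants3, R=np.eye(3))
        st_ = ScoreStats(trait="t", gene="g", variants=variants3,
                         U=np.zeros(3), V=np.eye(3),
                         maf=np.full(3, 0.01), n_samples=50)
        joint = assemble_joint([st_], np.eye(1), ld)
        spec = build_effect_kernel(0.5, 0.5, "iMTAR", maf=st_.maf,
                                   C=np.eye(1))
        q, p, _ = q_rho_test(joint, spec)
        assert q == 0.0 and p == 1.0

    def test_scalar_reduction(self):
        v = default_variants(1)
        ld = LDMatrix(variants=v, R=np.eye(1))
        st_ = ScoreStats(trait="t", gene="g", variants=v, U=np.array([1.7]),
                         V=np.array([[1.0]]), maf=np.array([0.01]),
                         n_samples=50)
        joint = assemble_joint([st_], np.eye(1), ld)
        q, p, _ = q_rho_test(joint, np.array([[1.0]]))
        assert q == pytest.approx(1.7**2)
        assert p == pytest.approx(stats.chi2.sf(1.7**2, 1), rel=1e-9)

    def test_skat_reduction_single_trait(self):
        st_, ld = make_single_trait_fixture()
        joint = assemble_joint([st_], np.eye(1), ld)
        w = variant_weights(st_.maf)
        spec = build_effect_kernel(0.0, 0.0, "iMTAR", weights=w,
                                   C=np.eye(1))
        q, p, _ = q_rho_test(joint, spec)
        # independently coded SKAT: Q = sum w^2 U^2, null weights from WVW
        q_skat = float(np.sum(w**2 * st_.U**2))
        lam = np.linalg.eigvalsh(st_.V * np.outer(w, w))
        p_skat = ruben_sf(q_skat, lam)
        assert q == pytest.approx(q_skat, rel=1e-10)
        assert p == pytest.approx(p_skat, abs=1e-8)

    def test_burden_reduction_single_trait(self):
        st_, ld = make_single_trait_fixture()
        joint = assemble_joint([st_], np.eye(1), ld)
        w = variant_weights(st_.maf)
        spec = build_effect_kernel(1.0, 0.0, "iMTAR", weights=w,
                                   C=np.eye(1))
        q, p, _ = q_rho_test(joint, spec)
        score = float(w @ st_.U)
        var = float(w @ st_.V @ w)
        assert q == pytest.approx(score**2, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(score**2 / var, 1), abs=1e-8)

    def test_monotone_in_effect_scale(self, rng):
        st_, ld = make_single_trait_fixture(seed=3, m=8)
        joint = assemble_joint([st_], np.eye(1), ld)
        spec = build_effect_kernel(0.5, 0.5, "iMTAR", maf=st_.maf,
                                   C=np.eye(1))
        q1, _, _ = q_rho_test(joint, spec)
        scaled = JointStats(traits=joint.traits, variants=joint.variants,
                            beta=2.0 * joint.beta, sigma=joint.sigma,
                            variant_index=joint.variant_index,
                            maf=joint.maf)
        q2, _, _ = q_rho_test(scaled, spec)
        assert q2 >= q1

    def test_dimension_mismatch_rejected(self):
        st_, ld = make_single_trait_fixture(seed=3, m=8)
        joint = assemble_joint([st_], np.eye(1), ld)
        with pytest.raises(ValueError, match="dimension"):
            q_rho_test(joint, np.eye(3))


def sympy_cauchy(ps):
    """50-digit evaluation of the Cauchy combination formula."""
    t = sum(sympy.tan((sympy.Rational(1, 2) - sympy.Float(p, 50))
                      * sympy.pi) for p in ps) / len(ps)
    return float(sympy.Rational(1, 2) - sympy.atan(t) / sympy.pi)


class TestCauchy:
    def test_idempotent_on_identical_pvalues(self):
        for p in (0.5, 0.01, 0.73, 1e-8):
            assert cauchy_combine([p, p, p]) == pytest.approx(p, abs=1e-12)

    def test_single_half(self):
        assert cauchy_combine([0.5]) == pytest.approx(0.5, abs=1e-15)

    def test_formula_against_high_precision(self):
        for ps in ([0.01, 0.5], [0.01, 0.2, 0.5], [0.3, 0.4, 0.9, 0.05]):
            assert cauchy_combine(ps) == pytest.approx(sympy_cauchy(ps),
                                                       abs=1e-12)

    def test_small_p_guard(self):
        # below 1e-16 the tangent switches to its asymptote 1/(p*pi)
        got = cauchy_combine([1e-20, 1e-20])
        assert got == pytest.approx(1e-20, rel=1e-6)

    def test_exact_one_clamped(self):
        assert 0.0 < cauchy_combine([1.0, 0.5]) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([0.5, 0.0])
        with pytest.raises(ValueError):
            cauchy_combine([0.5, 1.2])

    def test_weighted_combination(self):
        assert cauchy_combine([0.01, 0.5], weights=[1.0, 0.0]) == \
            pytest.approx(0.01, abs=1e-12)


class TestGridTest:
    def _joint(self):
        st_, ld = make_single_trait_fixture(seed=11, m=6)
        return assemble_joint([st_], np.eye(1), ld), st_

    def test_singleton_grid_equals_point(self):
        joint, st_ = self._joint()
        w = variant_weights(st_.maf)
        t, p, pts = mtar_grid_test(joint, "iMTAR", np.eye(1), w,
                                   grid=((0.5,), (0.5,)))
        assert len(pts) == 1
        assert p == pytest.approx(pts[(0.5, 0.5)][1], abs=1e-12)

    def test_default_grid_size(self):
        joint, st_ = self._joint()
        w = variant_weights(st_.maf)
        _, _, pts = mtar_grid_test(joint, "iMTAR", np.eye(1), w)
        assert len(pts) == 9

    def test_compositional_oracle(self):
        joint, st_ = self._joint()
        w = variant_weights(st_.maf)
        t, p, pts = mtar_grid_test(joint, "cMTAR", np.eye(1), w)
        recomputed = []
        for (r1, r2) in pts:
            spec = build_effect_kernel(r1, r2, "cMTAR", weights=w,
                                       C=np.eye(1))
            recomputed.append(q_rho_test(joint, spec)[1])
        assert p == pytest.approx(cauchy_combine(recomputed), abs=1e-12)

    def test_empty_grid_rejected(self):
        joint, st_ = self._joint()
        with pytest.raises(ValueError, match="nonempty"):
            mtar_grid_test(joint, "iMTAR", np.eye(1),
                           variant_weights(st_.maf), grid=((), ()))


class TestSingleTraitAndOmnibus:
    def test_k1_cctp_is_two_test_combination(self):
        st_, _ = make_single_trait_fixture(seed=5, m=10)
        w = variant_weights(st_.maf)
        p_skat, p_burden, q_cctp, p_cctp, _ = single_trait_tests([st_], [w])
        assert p_cctp == pytest.approx(
            cauchy_combine([p_skat[0], p_burden[0]]), abs=1e-12)

    def test_duplicated_traits_match_single(self):
        st_, _ = make_single_trait_fixture(seed=5, m=10)
        w = variant_weights(st_.maf)
        _, _, _, p1, _ = single_trait_tests([st_], [w])
        _, _, _, p3, _ = single_trait_tests([st_, st_, st_], [w, w, w])
        assert p3 == pytest.approx(p1, abs=1e-12)

    def test_cctp_formula_oracle(self):
        # Q_cctP over 2K = 4 P-values, then 0.5 - arctan(Q)/pi
        ps = [0.01, 0.2, 0.03, 0.5]
        t = cauchy_statistic(ps)
        assert 0.5 - math.atan(t) / math.pi == pytest.approx(
            sympy_cauchy(ps), abs=1e-12)

    def test_zero_burden_variance_flagged(self, variants3):
        st_ = ScoreStats(trait="t", gene="g", variants=variants3,
                         U=np.zeros(3), V=np.zeros((3, 3)),
                         maf=np.full(3, 0.01), n_samples=10)
        _, p_burden, _, _, flags = single_trait_tests([st_], [np.ones(3)])
        assert p_burden[0] == 1.0
        assert "zero_burden_variance" in flags

    def test_omnibus_identical_components(self):
        q, p, _ = omnibus(0.07, 0.07, 0.07, [0.5, 0.5])
        assert p == pytest.approx(0.07, abs=1e-12)

    def test_omnibus_formula_oracle(self):
        q, p, _ = omnibus(0.01, 0.2, 0.5, [0.5, 0.5])
        assert p == pytest.approx(sympy_cauchy([0.01, 0.2, 0.5]), abs=1e-12)

    def test_minp_bonferroni_cap(self):
        _, _, minp = omnibus(0.5, 0.5, 0.5, [0.5, 0.5])
        assert minp == 1.0

    def test_minp_multiplicity(self):
        _, _, minp = omnibus(0.5, 0.5, 0.5, [0.01, 0.4, 0.2, 0.9])
        assert minp == pytest.approx(0.04)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="cMTAR"):
            omnibus(None, 0.1, 0.1, [0.5])


class TestFullBattery:
    def _two_trait_inputs(self, seed=23):
        rng = np.random.default_rng(seed)
        n, m = 500, 5
        g = rng.binomial(2, 0.04, size=(n, m)).astype(float)
        while np.any(g.std(axis=0) == 0):
            g = rng.binomial(2, 0.04, size=(n, m)).astype(float)
        variants = default_variants(m)
        stats = []
        for k in range(2):
            y = rng.standard_normal(n)
            resid = y - y.mean()
            a = np.mean(resid**2)
            gc = g - g.mean(axis=0)
            stats.append(ScoreStats(
                trait=f"t{k+1}", gene="g", variants=variants,
                U=g.T @ resid / a, V=gc.T @ gc / a,
                maf=g.mean(axis=0) / 2.0, n_samples=n))
        ld = LDMatrix(variants=variants, R=np.corrcoef(g, rowvar=False))
        return stats, ld

    def test_single_trait_imtar_equals_cmtar(self):
        st_, ld = make_single_trait_fixture(seed=9, m=6)
        res = mtar_gene_test([st_], ld, np.eye(1), C=np.eye(1))
        assert res.p_imtar == pytest.approx(res.p_cmtar, rel=1e-10)

    def test_homogeneous_limit_is_overall_burden(self):
        # cMTAR at (rho1, rho2) = (1, 0): Q equals the squared overall
        # weighted burden score across traits
        stats_, ld = self._two_trait_inputs()
        c = np.array([[1.0, 0.3], [0.3, 1.0]])
        res = mtar_gene_test(stats_, ld, np.eye(2), C=c)
        joint = assemble_joint(stats_, np.eye(2), ld)
        w = variant_weights(joint.maf)
        v = np.concatenate([w, w])
        z = np.linalg.solve(joint.sigma, joint.beta)
        q_expect = float(v @ z) ** 2
        q_got = res.per_point[("cMTAR", 1.0, 0.0)][0]
        assert q_got == pytest.approx(q_expect, rel=1e-8)

    def test_pvalues_in_unit_interval(self):
        stats_, ld = self._two_trait_inputs(seed=31)
        res = mtar_gene_test(stats_, ld, np.eye(2),
                             C=np.array([[1.0, -0.5], [-0.5, 1.0]]))
        for p in (res.p_mtar_o, res.p_cmtar, res.p_imtar, res.p_cctp,
                  res.p_minp, *res.p_skat, *res.p_burden):
            assert 0.0 < p <= 1.0
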