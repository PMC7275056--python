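"""Simulation harness: genotypes, overlapping-cohort phenotypes, power.

Genotypes are formed by resampling pairs of haplotypes from a finite pool
(100 haplotypes spanning 1 Mb by default) whose site frequencies follow a
1/x site-frequency spectrum truncated to the rare range; linkage
disequilibrium arises from the finite pool. Each simulated gene is a 3 kb
window restricted to rare variants (MAF < 5%). Three continuous traits are
generated from a multi-response regression with residual covariance
calibrated to three plasma lipid traits (LDL, HDL, TG), a binary and a
standard-normal covariate, and genetic effects
beta_kj = s_j^snp * s_k^trait * d * |log10 MAF_j| on the causal variants.
Cohorts measure different trait subsets, inducing the sample-overlap
structure consumed by the trait-covariance module. ``run_study`` runs the
whole pipeline per replicate (score statistics per cohort, fixed-effects
meta-analysis across cohorts, joint assembly, full test battery) and
reports empirical rejection rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_tests import mtar_gene_test
from .kernels import DEFAULT_GRID
from .sumstats import ScoreStats, _gaussian_uv, ld_from_reference
from .trait_cov import OverlapCounts, TraitCovariance, joint_from_uv, \
    zeta_analytic

log = logging.getLogger(__name__)

__all__ = [
    "HaplotypePool",
    "StudyDesign",
    "EffectConfig",
    "PhenotypeModel",
    "RegionGenotypes",
    "LIPID_GENETIC_CORRELATION",
    "TRAIT_PATTERNS",
    "generate_haplotype_pool",
    "generate_cohort_genotypes",
    "generate_phenotypes",
    "design_zeta",
    "run_study",
]

#: genome-wide genetic-correlation estimates among the three plasma lipid
#: traits (order LDL, HDL, TG) used throughout the worked examples:
#: 0.09 for (LDL, HDL), 0.35 for (LDL, TG), -0.61 for (HDL, TG).
LIPID_GENETIC_CORRELATION = np.array([
    [1.00, 0.09, 0.35],
    [0.09, 1.00, -0.61],
    [0.35, -0.61, 1.00],
])

#: the five among-trait effect-direction patterns of the power study
TRAIT_PATTERNS = [
    (0, 0, 1),
    (0, 1, 1),
    (0, -1, 1),
    (1, -1, 1),
    (1, 1, 1),
]

ALL_TESTS = ("MTAR-O", "cMTAR", "iMTAR", "cctP", "minP")


@dataclass
class HaplotypePool:
    """Binary haplotype pool with site positions and pool frequencies."""

    haplotypes: np.ndarray  # H x S, uint8
    positions: np.ndarray   # bp, sorted
    region_length: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def generate_haplotype_pool(n_sites: int = 5000,
                            region_length: int = 1_000_000,
                            n_haplotypes: int = 100,
                            max_maf: float = 0.05,
                            rng=None, seed=None) -> HaplotypePool:
    """Haplotype pool with a truncated 1/x site-frequency spectrum.

    Each site carries the derived allele on c of the H haplotypes, with c
    drawn proportional to 1/c on {1, ..., floor(H * max_maf)}; carriers are
    assigned uniformly at random and positions are uniform on the region.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if rng is None:
        rng = np.random.default_rng(seed)
    c_max = max(1, int(np.floor(n_haplotypes * max_maf)))
    counts = np.arange(1, c_max + 1)
    probs = (1.0 / counts) / np.sum(1.0 / counts)
    site_counts = rng.choice(counts, size=n_sites, p=probs)
    hap = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    for j, c in enumerate(site_counts):
        hap[rng.choice(n_haplotypes, size=c, replace=False), j] = 1
    if n_sites > region_length:
        raise ValueError("more sites than base pairs in the region")
    positions = np.sort(rng.choice(region_length, size=n_sites,
                                   replace=False) + 1)
    return HaplotypePool(haplotypes=hap, positions=positions,
                         region_length=region_length)


@dataclass
class StudyDesign:
    """Cohort sizes and the cohort-by-trait availability pattern.

    The default mirrors a three-cohort study (N1 = 3000, N2 = 3500,
    N3 = 2000) where cohort 1 measures all three traits, cohort 2 traits
    {1, 2} and cohort 3 trait {3}.
    """

    cohort_sizes: tuple = (3000, 3500, 2000)
    availability: np.ndarray = field(
        default_factory=lambda: np.array([[1, 1, 1], [1, 1, 0], [0, 0, 1]]))
    region_length: int = 3000
    m_variants: int | None = 10

    def __post_init__(self) -> None:
        self.availability = np.atleast_2d(np.asarray(self.availability, int))
        if self.availability.shape[0] != len(self.cohort_sizes):
            raise ValueError("availability must have one row per cohort")

    @property
    def n_traits(self) -> int:
        return self.availability.shape[1]

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    def trait_sample_size(self, k: int) -> int:
        return int(sum(n for n, a in zip(self.cohort_sizes,
                                         self.availability[:, k]) if a))

    def overlap_counts(self, k: int, kp: int, cor: float = 0.0
                       ) -> OverlapCounts:
        both = self.availability[:, k] & self.availability[:, kp]
        n_c = int(sum(n for n, b in zip(self.cohort_sizes, both) if b))
        return OverlapCounts(n_a=self.trait_sample_size(k),
                             n_b=self.trait_sample_size(kp), n_c=n_c,
                             cor=cor)


@dataclass
class PhenotypeModel:
    """Multi-response regression generating the correlated traits.

    Y_ik = sum_j beta_kj G_ij + 0.1 * X_i1 + 0.2 * X_i2 + eps_ik with
    X_i1 ~ Bernoulli(0.5), X_i2 ~ N(0, 1) and eps_i multivariate normal
    with the lipid-calibrated residual covariance.
    """

    covariate_effects: tuple = (0.1, 0.2)
    residual_cov: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.1, 0.0], [0.1, 1.0, -0.1], [0.0, -0.1, 1.0]]))

    def __post_init__(self) -> None:
        self.residual_cov = np.atleast_2d(np.asarray(self.residual_cov,
                                                     float))
        vals = np.linalg.eigvalsh(self.residual_cov)
        if vals.min() < -1e-10:
            raise ValueError("residual covariance must be PSD")
        self._chol = np.linalg.cholesky(self.residual_cov)

    @property
    def n_traits(self) -> int:
        return self.residual_cov.shape[0]

    def residual_cor(self, k: int, kp: int) -> float:
        c = self.residual_cov
        return float(c[k, kp] / np.sqrt(c[k, k] * c[kp, kp]))


@dataclass
class EffectConfig:
    """Causal configuration of the power study.

    beta_kj = s_j^snp * s_k^trait * d * |log10 MAF_j| on the causal set
    (sampled without replacement), 0 elsewhere. The causal set is shared by
    every trait with nonzero pattern entry.
    """

    d: float
    causal_fraction: float = 0.5
    trait_pattern: tuple = (1, 1, 1)
    snp_sign: str = "fixed"  # "fixed" (+1) or "random" (+-1)
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal fraction must lie in [0, 1]")
        if self.snp_sign not in ("fixed", "random"):
            raise ValueError("snp_sign must be 'fixed' or 'random'")
        if self.label is None:
            self.label = (f"pattern={self.trait_pattern}, "
                          f"causal={self.causal_fraction:g}, d={self.d:g}, "
                          f"signs={self.snp_sign}")

    def draw_beta(self, maf: np.ndarray, rng) -> np.ndarray:
        """K x m effect matrix for one replicate."""
        m = maf.size
        k = len(self.trait_pattern)
        beta = np.zeros((k, m))
        if self.d == 0.0 or self.causal_fraction == 0.0:
            return beta
        n_causal = max(1, int(round(self.causal_fraction * m)))
        causal = rng.choice(m, size=n_causal, replace=False)
        s_snp = np.ones(n_causal)
        if self.snp_sign == "random":
            s_snp = rng.choice([-1.0, 1.0], size=n_causal)
        magnitude = self.d * np.abs(np.log10(maf[causal]))
        for ki, s_t in enumerate(self.trait_pattern):
            if s_t != 0:
                beta[ki, causal] = s_t * s_snp * magnitude
        return beta


NULL_CONFIG = EffectConfig(d=0.0, causal_fraction=0.0, label="null")


@dataclass
class RegionGenotypes:
    """Genotypes of one sampled gene region across the cohorts."""

    genotypes: list            # per-cohort n_c x m matrices
    maf: np.ndarray            # combined-sample MAF
    variants: pd.DataFrame
    ld: object                 # LDMatrix on the kept variants
    window_start: int


def generate_cohort_genotypes(pool: HaplotypePool, design: StudyDesign,
                              rng, max_maf: float = 0.05,
                              max_retries: int = 50,
                              dedup_r: float = 0.9999) -> RegionGenotypes:
    """Sample a gene window and form cohort genotypes from the pool.

    Each subject is the sum of two haplotypes drawn uniformly with
    replacement. Sites monomorphic in the combined sample or exceeding the
    rare-variant MAF cap are dropped, as is one member of any variant pair
    in (near-)perfect LD. Windows with fewer than 2 usable rare sites are
    resampled up to ``max_retries`` times.
    """
    hap = pool.haplotypes
    for _ in range(max_retries):
        start = int(rng.integers(0, max(1, pool.region_length
                                        - design.region_length)))
        in_win = np.flatnonzero((pool.positions >= start)
                                & (pool.positions < start
                                   + design.region_length))
        if in_win.size < 2:
            continue
        sub = hap[:, in_win]
        genos = []
        for n in design.cohort_sizes:
            idx = rng.integers(0, pool.n_haplotypes, size=(n, 2))
            genos.append((sub[idx[:, 0]] + sub[idx[:, 1]]).astype(np.float64))
        combined = np.vstack(genos)
        freq = combined.mean(axis=0) / 2.0
        keep = (freq > 0.0) & (freq < max_maf)
        if keep.sum() < 2:
            continue
        combined = combined[:, keep]
        sites = in_win[keep]
        # drop duplicated columns in (near-)perfect LD: they make V singular
        r = np.corrcoef(combined, rowvar=False)
        keep2 = []
        for j in range(combined.shape[1]):
            if all(abs(r[j, i]) < dedup_r for i in keep2):
                keep2.append(j)
        if len(keep2) < 2:
            continue
        if design.m_variants is not None and len(keep2) > design.m_variants:
            chosen = sorted(rng.choice(len(keep2), size=design.m_variants,
                                       replace=False).tolist())
            keep2 = [keep2[i] for i in chosen]
        sel = np.asarray(keep2, int)
        combined = combined[:, sel]
        sites = sites[sel]
        genos = [g[:, keep][:, sel] for g in genos]
        variants = pd.DataFrame({
            "chrom": "1",
            "pos": pool.positions[sites],
            "ref": "A",
            "alt": "C",
        })
        ld = ld_from_reference(combined, variants)
        return RegionGenotypes(genotypes=genos,
                               maf=combined.mean(axis=0) / 2.0,
                               variants=variants, ld=ld, window_start=start)
    raise RuntimeError("no window with >= 2 polymorphic rare variants after "
                       f"{max_retries} retries")


def generate_phenotypes(region: RegionGenotypes, design: StudyDesign,
                        beta: np.ndarray, model: PhenotypeModel, rng):
    """Per-cohort phenotype and covariate tables.

    Returns a list (one entry per cohort) of dicts with keys ``Y`` (n x K,
    NaN for unavailable traits), ``X`` (n x 3 design with intercept).
    """
    k_traits = model.n_traits
    out = []
    for c, (g, n) in enumerate(zip(region.genotypes, design.cohort_sizes)):
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.standard_normal(n)
        y = rng.standard_normal((n, k_traits)) @ model._chol.T
        if np.any(beta):
            y += g @ beta.T
        y += (model.covariate_effects[0] * x1
              + model.covariate_effects[1] * x2)[:, None]
        y[:, design.availability[c] == 0] = np.nan
        out.append({"Y": y, "X": np.column_stack([np.ones(n), x1, x2])})
    return out


def design_zeta(design: StudyDesign, model: PhenotypeModel
                ) -> TraitCovariance:
    """Analytic null Z-score covariance implied by the overlap design."""
    K = design.n_traits
    zeta = np.eye(K)
    for k in range(K):
        for kp in range(k + 1, K):
            counts = design.overlap_counts(k, kp, model.residual_cor(k, kp))
            zeta[k, kp] = zeta[kp, k] = zeta_analytic(counts)
    return TraitCovariance(traits=[f"trait{i+1}" for i in range(K)],
                           zeta=zeta, provenance="analytic")


def _meta_score_stats(region: RegionGenotypes, design: StudyDesign,
                      pheno: list, grams: list):
    """Per-trait (U, V) combined across cohorts by fixed-effects meta."""
    K = design.n_traits
    m = region.maf.size
    U = np.zeros((K, m))
    V = np.zeros((K, m, m))
    for c in range(design.n_cohorts):
        x = pheno[c]["X"]
        for k in range(K):
            if not design.availability[c, k]:
                continue
            u, v = _gaussian_uv(pheno[c]["Y"][:, k], x,
                                region.genotypes[c], gram=grams[c])
            U[k] += u
            V[k] += v
    return U, V


def _replicate_pvalues(region, design, model, cfg, zeta, C, grid,
                       weight_scheme, acc, rng, grams, kernel_cache, tests):
    """One replicate through the per-gene path (reference engine)."""
    key_map = {"MTAR-O": "p_mtar_o", "cMTAR": "p_cmtar", "iMTAR": "p_imtar",
               "cctP": "p_cctp", "minP": "p_minp"}
    beta = cfg.draw_beta(region.maf, rng)
    pheno = generate_phenotypes(region, design, beta, model, rng)
    U, V = _meta_score_stats(region, design, pheno, grams)
    stats = [
        ScoreStats(trait=f"trait{k+1}", gene="sim",
                   variants=region.variants, U=U[k], V=V[k],
                   maf=region.maf, n_samples=design.trait_sample_size(k))
        for k in range(design.n_traits)
    ]
    joint = joint_from_uv([st.U for st in stats], [st.V for st in stats],
                          zeta.zeta, region.ld.R, traits=zeta.traits,
                          variants=region.variants, maf=region.maf)
    res = mtar_gene_test(stats, region.ld, zeta, C=C,
                         weight_scheme=weight_scheme, grid=grid, acc=acc,
                         joint=joint, _kernels=kernel_cache)
    return {t: getattr(res, key_map[t]) for t in tests}


def _batch_pvalues(region, design, model, cfg, zeta, C, grid, weight_scheme,
                   acc, rng, grams, n_rep, tests):
    """A batch of replicates through the stacked fast engine."""
    from . import _batch
    from .kernels import variant_weights

    K = design.n_traits
    m = region.maf.size
    U = np.zeros((n_rep, K, m))
    V = np.zeros((n_rep, K, m, m))
    betas = np.stack([cfg.draw_beta(region.maf, rng) for _ in range(n_rep)])
    for c, (g, n_sub) in enumerate(zip(region.genotypes,
                                       design.cohort_sizes)):
        avail = np.flatnonzero(design.availability[c])
        x1 = (rng.random((n_rep, n_sub)) < 0.5).astype(float)
        x2 = rng.standard_normal((n_rep, n_sub))
        y = rng.standard_normal((n_rep, n_sub, K)) @ model._chol.T
        if np.any(betas):
            y = y + np.einsum("nm,bkm->bnk", g, betas)
        y += (model.covariate_effects[0] * x1
              + model.covariate_effects[1] * x2)[:, :, None]
        u_c, v_c = _batch.cohort_scores_batch(y[:, :, avail], x1, x2, g,
                                              grams[c])
        U[:, avail] += u_c
        V[:, avail] += v_c
    w = variant_weights(region.maf, weight_scheme)
    out = _batch.battery_batch(U, V, zeta.zeta, region.ld.R, C, w,
                               grid=grid, acc=acc)
    return {t: out[t] for t in tests}


def run_study(design: StudyDesign, effect_configs, alpha: float,
              n_replicates: int, seed: int, pool: HaplotypePool | None = None,
              model: PhenotypeModel | None = None, C=None,
              grid=DEFAULT_GRID, weight_scheme: str = "beta_1_25",
              tests=ALL_TESTS, n_regions: int = 100, acc: float = 1e-6,
              return_pvalues: bool = False, engine: str = "batched",
              batch_size: int = 250):
    """Empirical rejection rates of the test battery per configuration.

    Per replicate: generate phenotypes on the current gene region, compute
    per-cohort score statistics, combine across cohorts (sum of U, sum of
    V), assemble the joint statistics with the design-implied analytic zeta,
    and run all tests. A fresh gene region is sampled every
    ``n_replicates / n_regions`` replicates. Identical seeds give identical
    tables for a given engine; the stacked default engine computes the same
    P-values as the per-gene path (asserted by the test suite).
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    if engine not in ("batched", "perrep"):
        raise ValueError("engine must be 'batched' or 'perrep'")
    if model is None:
        model = PhenotypeModel()
    if C is None:
        C = LIPID_GENETIC_CORRELATION[:design.n_traits, :design.n_traits]
    if effect_configs is None:
        effect_configs = [NULL_CONFIG]
    if isinstance(effect_configs, EffectConfig):
        effect_configs = [effect_configs]
    zeta = design_zeta(design, model)
    reps_per_region = max(1, int(np.ceil(n_replicates / n_regions)))
    ss = np.random.SeedSequence(seed)
    child_seqs = ss.spawn(len(effect_configs) + 1)
    pool_rng = np.random.default_rng(child_seqs[-1])
    if pool is None:
        pool = generate_haplotype_pool(rng=pool_rng)
    rows = []
    pvalue_store: dict = {}
    for cfg, seq in zip(effect_configs, child_seqs):
        rng = np.random.default_rng(seq)
        pvals = {t: np.empty(n_replicates) for t in tests}
        region = None
        kernel_cache: dict = {}
        rep = 0
        while rep < n_replicates:
            if rep % reps_per_region == 0:
                region = generate_cohort_genotypes(pool, design, rng)
                grams = [g.T @ g for g in region.genotypes]
                kernel_cache = {}
            if engine == "batched":
                n_now = min(reps_per_region - rep % reps_per_region,
                            n_replicates - rep, batch_size)
                got = _batch_pvalues(region, design, model, cfg, zeta, C,
                                     grid, weight_scheme, acc, rng, grams,
                                     n_now, tests)
                for t in tests:
                    pvals[t][rep:rep + n_now] = got[t]
                rep += n_now
            else:
                got = _replicate_pvalues(region, design, model, cfg, zeta,
                                         C, grid, weight_scheme, acc, rng,
                                         grams, kernel_cache, tests)
                for t in tests:
                    pvals[t][rep] = got[t]
                rep += 1
        for t in tests:
            n_rej = int(np.sum(pvals[t] < alpha))
            rate = n_rej / n_replicates
            rows.append({
                "config": cfg.label,
                "pattern": str(tuple(cfg.trait_pattern)),
                "causal_fraction": cfg.causal_fraction,
                "d": cfg.d,
                "test": t,
                "alpha": alpha,
                "n_replicates": n_replicates,
                "n_reject": n_rej,
                "rate": rate,
                "se": float(np.sqrt(max(rate * (1 - rate), 1e-300)
                                    / n_replicates)),
            })
        if return_pvalues:
            pvalue_store[cfg.label] = pvals
    table = pd.DataFrame(rows)
    if return_pvalues:
        return table, pvalue_store
    return table
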