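"""Per-trait variant-level score statistics U and their covariance V.

Gene-level multi-trait tests consume, for every trait k, the score vector
U_k for H0: beta_k = 0 from a generalized linear model and its covariance
V_k. These are computed directly when individual-level data are available,
or reconstructed from routinely shared summary formats (effect estimates
with standard errors, or scores with variances) together with an LD
correlation matrix R from a reference panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

log = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "ScoreStats",
    "EffectSummary",
    "LDMatrix",
    "score_stats_from_individual_data",
    "reconstruct_uv",
    "ld_from_reference",
    "variant_ids",
]

VARIANT_COLS = ["chrom", "pos", "ref", "alt"]

#: complementary bases, used to detect strand-ambiguous (A/T, C/G) pairs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical 'chrom:pos:ref:alt' identifiers for a variant table."""
    v = variants
    return pd.Index(v["chrom"].astype(str) + ":" + v["pos"].astype(str)
                    + ":" + v["ref"].astype(str) + ":" + v["alt"].astype(str))


@dataclass
class CohortData:
    """Individual-level inputs for one trait in one cohort.

    phenotype: length-n vector (continuous, or 0/1 for binomial family).
    genotypes: n x m matrix of minor-allele counts in {0, 1, 2}; missing
        entries should be mean-imputed before construction.
    covariates: n x q design including an intercept column.
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    covariates: np.ndarray
    family: str = "gaussian"

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float).ravel()
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=float))
        self.covariates = np.atleast_2d(np.asarray(self.covariates,
                                                   dtype=float))
        n = self.phenotype.size
        if self.genotypes.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("phenotype, genotypes and covariates must share "
                             "the sample dimension")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if self.family == "binomial":
            vals = np.unique(self.phenotype)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binomial phenotype must be coded 0/1")
            if vals.size < 2:
                raise ValueError("binary phenotype contains a single class")
        if n < self.covariates.shape[1] + 1:
            raise ValueError("need more subjects than covariates")


@dataclass
class ScoreStats:
    """Score statistics for one trait at one gene."""

    trait: str
    gene: str
    variants: pd.DataFrame
    U: np.ndarray
    V: np.ndarray
    maf: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float).ravel()
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.maf = np.asarray(self.maf, dtype=float).ravel()
        m = self.U.size
        if self.V.shape != (m, m):
            raise ValueError("V must be m x m")
        if not np.allclose(self.V, self.V.T, atol=1e-8 * max(
                1.0, float(np.abs(self.V).max()))):
            raise ValueError("V must be symmetric")

    @property
    def n_variants(self) -> int:
        return self.U.size

    @property
    def ids(self) -> pd.Index:
        return variant_ids(self.variants)


@dataclass
class EffectSummary:
    """Per-variant effect estimates and standard errors for one trait."""

    trait: str
    gene: str
    variants: pd.DataFrame
    beta: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.se = np.asarray(self.se, dtype=float).ravel()
        self.maf = np.asarray(self.maf, dtype=float).ravel()
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def ids(self) -> pd.Index:
        return variant_ids(self.variants)


@dataclass
class LDMatrix:
    """Pearson genotype correlations among the variants of a gene."""

    variants: pd.DataFrame
    R: np.ndarray
    dropped_monomorphic: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(self.R) > 1.0 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")

    @property
    def ids(self) -> pd.Index:
        return variant_ids(self.variants)


def _gaussian_uv(y: np.ndarray, x: np.ndarray, g: np.ndarray,
                 gram: np.ndarray | None = None):
    """Score vector and covariance for the linear model, H0: beta = 0.

    gram (G'G) may be precomputed when the same genotypes are reused across
    many phenotype draws.
    """
    n = y.size
    xtx = x.T @ x
    try:
        # cholesky doubles as the collinearity check (xtx must be SPD)
        cf = linalg.cho_factor(xtx)
        gamma = linalg.cho_solve(cf, x.T @ y)
    except (np.linalg.LinAlgError, linalg.LinAlgError) as exc:
        raise ValueError("covariates collinear") from exc
    resid = y - x @ gamma
    # ML dispersion estimate (divide by n) under the null model
    a_phi = float(resid @ resid) / n
    if a_phi <= 0:
        raise ValueError("degenerate phenotype: zero residual variance")
    u = (g.T @ resid) / a_phi
    gtx = g.T @ x
    if gram is None:
        gram = g.T @ g
    v = (gram - gtx @ linalg.cho_solve(cf, gtx.T)) / a_phi
    return u, 0.5 * (v + v.T)


def _binomial_uv(y: np.ndarray, x: np.ndarray, g: np.ndarray):
    """Score vector and covariance for the logistic model, H0: beta = 0."""
    import statsmodels.api as sm

    if np.linalg.matrix_rank(x.T @ x) < x.shape[1]:
        raise ValueError("covariates collinear")
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    mu = fit.predict(x)
    w = mu * (1.0 - mu)  # b''(eta); a(phi) = 1 for logistic
    u = g.T @ (y - mu)
    gw = g * w[:, None]
    xtwx = x.T @ (x * w[:, None])
    gtwx = gw.T @ x
    v = gw.T @ g - gtwx @ np.linalg.solve(xtwx, gtwx.T)
    return u, 0.5 * (v + v.T)


def score_stats_from_individual_data(cohort: CohortData, trait: str = "trait",
                                     gene: str = "gene",
                                     variants: pd.DataFrame | None = None
                                     ) -> ScoreStats:
    """Compute U_k and V_k from individual-level data under the null GLM.

    U_k = a(phi)^-1 * sum_i {Y_i - b'(gamma' X_i)} G_i and V_k is the
    genotype-block information with the genotype-covariate cross-information
    projected out. The gaussian family uses the ML residual variance as
    dispersion; the binomial family fixes the dispersion at 1.
    """
    y, x, g = cohort.phenotype, cohort.covariates, cohort.genotypes
    if cohort.family == "gaussian":
        u, v = _gaussian_uv(y, x, g)
    else:
        u, v = _binomial_uv(y, x, g)
    maf = g.mean(axis=0) / 2.0
    if variants is None:
        variants = default_variants(g.shape[1])
    return ScoreStats(trait=trait, gene=gene, variants=variants, U=u, V=v,
                      maf=maf, n_samples=y.size)


def default_variants(m: int, chrom: str = "1", start: int = 1,
                     spacing: int = 1) -> pd.DataFrame:
    """Placeholder variant keys for data without genomic coordinates."""
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(start, start + m * spacing, spacing),
        "ref": "A",
        "alt": "C",
    })


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


def _align_to_ld(summary_ids: pd.Index, variants: pd.DataFrame,
                 ld: LDMatrix):
    """Match summary variants to the LD reference by (chrom, pos, ref, alt).

    Returns (kept summary positions, LD positions, sign flips). Variants with
    alleles swapped relative to the reference are matched with a sign flip;
    variants absent from the reference are dropped with a warning.
    """
    ld_ids = ld.ids
    ld_lookup = {vid: i for i, vid in enumerate(ld_ids)}
    swapped_ids = variants["chrom"].astype(str) + ":" + \
        variants["pos"].astype(str) + ":" + variants["alt"].astype(str) + \
        ":" + variants["ref"].astype(str)
    keep, ld_pos, flip = [], [], []
    n_ambiguous = 0
    for i, (vid, sid) in enumerate(zip(summary_ids, swapped_ids)):
        if vid in ld_lookup:
            keep.append(i)
            ld_pos.append(ld_lookup[vid])
            flip.append(1.0)
        elif sid in ld_lookup:
            keep.append(i)
            ld_pos.append(ld_lookup[sid])
            flip.append(-1.0)
        if vid in ld_lookup and is_strand_ambiguous(
                str(variants["ref"].iloc[i]), str(variants["alt"].iloc[i])):
            n_ambiguous += 1
    n_dropped = len(summary_ids) - len(keep)
    if n_dropped:
        log.warning("%d variant(s) absent from the LD reference were dropped",
                    n_dropped)
    if n_ambiguous:
        log.warning("%d strand-ambiguous variant(s) kept as-is", n_ambiguous)
    return np.asarray(keep, int), np.asarray(ld_pos, int), np.asarray(flip)


def reconstruct_uv(summary, ld: LDMatrix) -> ScoreStats:
    """Reconstruct dense (U, V) from shared summary formats.

    From effect estimates: U_j ~= beta_j / se_j^2 and
    V_jl ~= R_jl / (se_j * se_l). From scores with variances only:
    V = diag(V)^{1/2} R diag(V)^{1/2}.
    """
    if isinstance(summary, EffectSummary):
        ids = summary.ids
        keep, ld_pos, flip = _align_to_ld(ids, summary.variants, ld)
        beta = summary.beta[keep] * flip
        se = summary.se[keep]
        maf = summary.maf[keep].copy()
        maf[flip < 0] = 1.0 - maf[flip < 0]
        u = beta / se**2
        dsq = 1.0 / se
        r = ld.R[np.ix_(ld_pos, ld_pos)]
        v = r * np.outer(dsq, dsq)
        variants = ld.variants.iloc[ld_pos].reset_index(drop=True)
        return ScoreStats(trait=summary.trait, gene=summary.gene,
                          variants=variants, U=u, V=v, maf=maf,
                          n_samples=summary.n_samples)
    if isinstance(summary, ScoreStats):
        ids = summary.ids
        keep, ld_pos, flip = _align_to_ld(ids, summary.variants, ld)
        u = summary.U[keep] * flip
        dv = np.diag(summary.V)[keep]
        if np.any(dv < 0):
            raise ValueError("negative score variances")
        maf = summary.maf[keep].copy()
        maf[flip < 0] = 1.0 - maf[flip < 0]
        d = np.sqrt(dv)
        r = ld.R[np.ix_(ld_pos, ld_pos)]
        v = r * np.outer(d, d)
        variants = ld.variants.iloc[ld_pos].reset_index(drop=True)
        return ScoreStats(trait=summary.trait, gene=summary.gene,
                          variants=variants, U=u, V=v, maf=maf,
                          n_samples=summary.n_samples)
    raise TypeError("summary must be an EffectSummary or ScoreStats")


def ld_from_reference(genotypes, variants: pd.DataFrame | None = None
                      ) -> LDMatrix:
    """Pearson correlation matrix of reference genotype columns.

    Monomorphic reference variants are excluded and reported on the result.
    """
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if g.shape[0] < 2:
        raise ValueError("need at least 2 reference samples to compute LD")
    if variants is None:
        variants = default_variants(g.shape[1])
    sd = g.std(axis=0)
    poly = sd > 0
    dropped = variants.loc[~poly].reset_index(drop=True)
    if dropped.shape[0]:
        log.warning("%d monomorphic reference variant(s) excluded from LD",
                    dropped.shape[0])
    g = g[:, poly]
    centered = g - g.mean(axis=0)
    denom = np.sqrt((centered**2).sum(axis=0))
    r = (centered.T @ centered) / np.outer(denom, denom)
    np.fill_diagonal(r, 1.0)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    return LDMatrix(variants=variants.loc[poly].reset_index(drop=True), R=r,
                    dropped_monomorphic=dropped)
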