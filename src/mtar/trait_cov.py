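"""Between-trait covariance of summary statistics under sample overlap.

When traits are measured on overlapping samples, the per-trait score
statistics are correlated. For a null variant the correlation zeta_kk' of
the Z-scores between traits k and k' does not depend on the variant: for two
quantitative traits zeta ~= n_C * cor(Y_k, Y_k') / sqrt(n_A * n_B), and an
analogous count-based formula holds for two binary traits. zeta can also be
estimated empirically as the sample correlation of genome-wide Z-scores over
LD-pruned variants not associated with any trait. Together with the per-gene
LD matrix R, zeta determines the cross-trait blocks of the covariance Sigma
of the stacked effect estimates beta_hat_k = V_k^{-1} U_k:

    cov(beta_hat_k, beta_hat_k') ~=
        zeta_kk' V_k^{-1} diag(V_k)^{1/2} R diag(V_k')^{1/2} V_k'^{-1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, ScoreStats

log = logging.getLogger(__name__)

__all__ = [
    "OverlapCounts",
    "TraitCovariance",
    "JointStats",
    "zeta_analytic",
    "zeta_empirical",
    "assemble_joint",
    "joint_from_uv",
    "ld_prune",
    "repair_psd",
]


@dataclass
class OverlapCounts:
    """Cohort sizes and overlap between the samples of two traits."""

    n_a: int
    n_b: int
    n_c: int
    cor: float = 0.0  # phenotypic correlation on the overlap (quantitative)
    # class counts for binary/binary pairs
    n_a0: int | None = None
    n_a1: int | None = None
    n_b0: int | None = None
    n_b1: int | None = None
    n_c0: int | None = None
    n_c1: int | None = None

    def __post_init__(self) -> None:
        if self.n_c > min(self.n_a, self.n_b):
            raise ValueError("overlap cannot exceed either cohort size")
        if not -1.0 <= self.cor <= 1.0:
            raise ValueError("phenotypic correlation must lie in [-1, 1]")


def zeta_analytic(counts: OverlapCounts,
                  families=("gaussian", "gaussian")) -> float:
    """Analytic null Z-score covariance for a pair of same-type traits."""
    fam = tuple(families)
    if fam == ("gaussian", "gaussian"):
        if counts.n_c == 0:
            return 0.0
        return counts.n_c / (np.sqrt(counts.n_a) * np.sqrt(counts.n_b)) \
            * counts.cor
    if fam == ("binomial", "binomial"):
        needed = (counts.n_a0, counts.n_a1, counts.n_b0, counts.n_b1,
                  counts.n_c0, counts.n_c1)
        if any(v is None for v in needed):
            raise ValueError("binary pair requires the six class counts")
        n_a0, n_a1, n_b0, n_b1, n_c0, n_c1 = (float(v) for v in needed)
        if n_a0 + n_a1 != counts.n_a or n_b0 + n_b1 != counts.n_b:
            raise ValueError("class counts must sum to cohort sizes")
        if n_c0 + n_c1 == 0:
            return 0.0
        return (n_c0 * np.sqrt(n_a1 * n_b1 / (n_a0 * n_b0))
                + n_c1 * np.sqrt(n_a0 * n_b0 / (n_a1 * n_b1))) \
            / np.sqrt(counts.n_a * counts.n_b)
    raise ValueError("no analytic formula for a mixed quantitative/binary "
                     "pair; use zeta_empirical")


@dataclass
class TraitCovariance:
    """K x K matrix of null Z-score covariances with unit diagonal."""

    traits: list[str]
    zeta: np.ndarray
    provenance: str = "analytic"
    n_variants_used: int | None = None

    def __post_init__(self) -> None:
        z = np.atleast_2d(np.asarray(self.zeta, dtype=float))
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("zeta must be symmetric")
        if not np.allclose(np.diag(z), 1.0, atol=1e-8):
            raise ValueError("zeta must have unit diagonal")
        if np.any(np.abs(z) > 1.0 + 1e-8):
            raise ValueError("zeta entries must lie in [-1, 1]")
        self.zeta = repair_psd(z, rescale_diag=True)

    @classmethod
    def identity(cls, traits: list[str]) -> "TraitCovariance":
        return cls(traits=list(traits), zeta=np.eye(len(traits)),
                   provenance="analytic")


def repair_psd(a: np.ndarray, rescale_diag: bool = False,
               tol: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues to zero; optionally restore the diagonal."""
    a = 0.5 * (a + a.T)
    vals, vecs = np.linalg.eigh(a)
    if vals.min() >= tol:
        return a
    fixed = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    if rescale_diag:
        d_old = np.diag(a).copy()
        d_new = np.diag(fixed).copy()
        ok = d_new > 0
        scale = np.ones_like(d_new)
        scale[ok] = np.sqrt(d_old[ok] / d_new[ok])
        fixed = fixed * np.outer(scale, scale)
    return 0.5 * (fixed + fixed.T)


def ld_prune(positions, genotypes, r2_threshold: float = 0.01,
             window_bp: int = 500_000) -> np.ndarray:
    """Greedy LD pruning scanning by position.

    Keeps a variant unless its squared correlation with an already-kept
    variant within ``window_bp`` reaches ``r2_threshold``. Returns indices
    (into the original order) of the retained variants.
    """
    pos = np.asarray(positions)
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    order = np.argsort(pos, kind="stable")
    centered = g - g.mean(axis=0)
    norm = np.sqrt((centered**2).sum(axis=0))
    kept: list[int] = []
    kept_pos: list[int] = []
    for i in order:
        if norm[i] == 0:
            continue  # monomorphic: uninformative for pruning purposes
        ok = True
        for j, pj in zip(reversed(kept), reversed(kept_pos)):
            if pos[i] - pj > window_bp:
                break
            r = float(centered[:, i] @ centered[:, j]) / (norm[i] * norm[j])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
            kept_pos.append(pos[i])
    return np.sort(np.asarray(kept, dtype=int))


def zeta_empirical(zscores: dict[str, pd.DataFrame],
                   reference_genotypes=None,
                   reference_variants: pd.DataFrame | None = None,
                   r2_threshold: float = 0.01, window_bp: int = 500_000,
                   p_threshold: float = 0.05, maf_min: float = 0.01,
                   min_variants: int = 1000) -> TraitCovariance:
    """Estimate zeta from genome-wide per-variant Z-scores.

    Keeps common variants (MAF >= ``maf_min`` when a MAF column is present),
    LD-prunes against ``reference_genotypes`` when supplied (otherwise the
    variants are assumed independent), removes variants associated with any
    trait (P < ``p_threshold`` in any trait; missing P-values pass, logged),
    then returns pairwise sample correlations of the surviving Z-scores.

    Each table must have columns CHR, POS, Z and optionally P and MAF.
    """
    traits = list(zscores)
    key = ["CHR", "POS"]
    frames = {}
    for t in traits:
        df = zscores[t].copy()
        if "MAF" in df.columns:
            df = df[df["MAF"] >= maf_min]
        if "P" not in df.columns:
            log.warning("trait %s has no P column; association filter "
                        "treats all variants as null", t)
            df["P"] = 1.0
        else:
            n_missing = int(df["P"].isna().sum())
            if n_missing:
                log.warning("trait %s: %d missing P-values treated as pass",
                            t, n_missing)
            df["P"] = df["P"].fillna(1.0)
        frames[t] = df.set_index(key)

    # "not associated with any traits": a variant fails if P < threshold in
    # any trait where it is observed
    bad: set = set()
    for t in traits:
        df = frames[t]
        bad |= set(df.index[df["P"] < p_threshold])
    for t in traits:
        frames[t] = frames[t][~frames[t].index.isin(bad)]

    if reference_genotypes is not None:
        if reference_variants is None:
            raise ValueError("reference_variants required with reference "
                             "genotypes")
        kept = ld_prune(reference_variants["pos"].to_numpy(),
                        reference_genotypes, r2_threshold, window_bp)
        kept_keys = set(zip(reference_variants["chrom"].astype(str).iloc[kept],
                            reference_variants["pos"].iloc[kept]))
        for t in traits:
            idx = frames[t].index
            mask = [(str(c), p) in kept_keys for c, p in idx]
            frames[t] = frames[t][np.asarray(mask, bool)]

    K = len(traits)
    zeta = np.eye(K)
    n_used = None
    for i in range(K):
        for j in range(i + 1, K):
            merged = frames[traits[i]][["Z"]].join(
                frames[traits[j]][["Z"]], how="inner", lsuffix="_a",
                rsuffix="_b").dropna()
            m = merged.shape[0]
            if m < min_variants:
                raise ValueError(
                    f"only {m} variants survive filtering for pair "
                    f"({traits[i]}, {traits[j]}); need >= {min_variants}")
            n_used = m if n_used is None else min(n_used, m)
            z = float(np.corrcoef(merged["Z_a"], merged["Z_b"])[0, 1])
            zeta[i, j] = zeta[j, i] = z
    return TraitCovariance(traits=traits, zeta=zeta, provenance="empirical",
                           n_variants_used=n_used)


@dataclass
class JointStats:
    """Stacked effect estimates across traits with their full covariance.

    Ordering is trait-major: all (present) variants of trait 1, then trait 2,
    and so on. ``trait_slices`` give each trait's rows and ``variant_index``
    maps each trait's rows into the union variant set of the gene (traits may
    lack variants that are monomorphic in their sample).
    """

    traits: list[str]
    variants: pd.DataFrame
    beta: np.ndarray
    sigma: np.ndarray
    variant_index: list[np.ndarray]
    maf: np.ndarray
    field_notes: dict = field(default_factory=dict)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_variants(self) -> int:
        return self.variants.shape[0]

    def trait_slices(self) -> list[slice]:
        out, start = [], 0
        for idx in self.variant_index:
            out.append(slice(start, start + idx.size))
            start += idx.size
        return out


def _inv_with_ridge(v: np.ndarray, note: dict) -> np.ndarray:
    """Inverse of V with a tiny ridge when numerically singular."""
    from scipy import linalg as _sla

    m = v.shape[0]
    try:
        cf = _sla.cho_factor(v, check_finite=False)
        inv = _sla.cho_solve(cf, np.eye(m), check_finite=False)
        # a huge inverse norm signals near-singularity the cholesky missed
        if np.isfinite(inv).all() and \
                np.abs(inv).max() * np.abs(v).max() < 1e14:
            return inv
    except (np.linalg.LinAlgError, _sla.LinAlgError):
        pass
    ridge = 1e-8 * float(np.mean(np.diag(v))) if np.any(np.diag(v) > 0) \
        else 1e-8
    log.warning("singular V: adding ridge %.3g to the diagonal", ridge)
    note["ridge"] = note.get("ridge", 0) + 1
    v = v + ridge * np.eye(m)
    while np.linalg.cond(v) > 1e14:
        ridge *= 10.0
        v = v + ridge * np.eye(m)
    return np.linalg.inv(v)


def joint_from_uv(U_list, V_list, zeta: np.ndarray, R: np.ndarray,
                  traits=None, variants: pd.DataFrame | None = None,
                  variant_index=None, maf=None) -> JointStats:
    """Assemble beta_hat and Sigma from per-trait (U, V) on a shared gene.

    ``variant_index`` maps each trait's variants into the union set indexing
    R; by default every trait covers the full set.
    """
    K = len(U_list)
    if traits is None:
        traits = [f"trait{k + 1}" for k in range(K)]
    m_union = R.shape[0]
    if variant_index is None:
        variant_index = [np.arange(m_union)] * K
    if variants is None:
        from .sumstats import default_variants
        variants = default_variants(m_union)
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if zeta.shape != (K, K):
        raise ValueError("zeta must be K x K; a pair is missing")
    notes: dict = {}
    vinv = [_inv_with_ridge(np.asarray(v, float), notes) for v in V_list]
    betas = [vi @ np.asarray(u, float) for vi, u in zip(vinv, U_list)]
    sizes = [u.size for u in betas]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    total = offs[-1]
    sigma = np.zeros((total, total))
    dhalf = [np.sqrt(np.clip(np.diag(np.asarray(v, float)), 0.0, None))
             for v in V_list]
    for k in range(K):
        sk = slice(offs[k], offs[k + 1])
        sigma[sk, sk] = vinv[k]
        for kp in range(k + 1, K):
            if zeta[k, kp] == 0.0:
                continue
            skp = slice(offs[kp], offs[kp + 1])
            r_blk = R[np.ix_(variant_index[k], variant_index[kp])]
            blk = zeta[k, kp] * vinv[k] @ (
                r_blk * np.outer(dhalf[k], dhalf[kp])) @ vinv[kp]
            sigma[sk, skp] = blk
            sigma[skp, sk] = blk.T
    sigma = repair_psd(sigma)
    if maf is None:
        maf = np.full(m_union, np.nan)
    return JointStats(traits=list(traits), variants=variants,
                      beta=np.concatenate(betas), sigma=sigma,
                      variant_index=[np.asarray(ix, int)
                                     for ix in variant_index],
                      maf=np.asarray(maf, float), field_notes=notes)


def assemble_joint(stats: list[ScoreStats], zeta: TraitCovariance | np.ndarray,
                   ld: LDMatrix) -> JointStats:
    """Assemble JointStats from harmonised per-trait ScoreStats and LD.

    The union variant set is taken from the LD matrix; every trait's variants
    must be a subset of it (harmonise first). With K = 1 Sigma reduces to
    V_1^{-1} exactly; with zero zeta off-diagonals Sigma is block-diagonal.
    """
    if isinstance(zeta, TraitCovariance):
        zmat = zeta.zeta
    else:
        zmat = np.atleast_2d(np.asarray(zeta, dtype=float))
    ld_lookup = {vid: i for i, vid in enumerate(ld.ids)}
    variant_index = []
    for st in stats:
        try:
            variant_index.append(
                np.asarray([ld_lookup[vid] for vid in st.ids], int))
        except KeyError as exc:
            raise ValueError(
                f"trait {st.trait}: variant {exc.args[0]} missing from the "
                "LD matrix; harmonise before assembly") from exc
    maf = np.full(ld.R.shape[0], np.nan)
    for st, ix in zip(stats, variant_index):
        maf[ix] = st.maf
    return joint_from_uv([st.U for st in stats], [st.V for st in stats],
                         zmat, ld.R, traits=[st.trait for st in stats],
                         variants=ld.variants, variant_index=variant_index,
                         maf=maf)
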