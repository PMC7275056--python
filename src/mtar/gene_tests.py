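"""Variance-component score tests and their Cauchy combinations.

For a fixed kernel B(rho1, rho2) the statistic

    Q_rho = beta_hat' Sigma^{-1} B Sigma^{-1} beta_hat

tests H0: sigma = 0 in the random-effects model beta ~ N(0, sigma * B) and
follows a mixture of chi-square distribution under the null, with weights
the eigenvalues of Sigma^{-1} B. The iMTAR and cMTAR tests combine the
P-values over a grid of (rho1, rho2) with the Cauchy method; cctP combines
the single-trait SKAT and burden P-values; MTAR-O combines cMTAR, iMTAR and
cctP; minP is the Bonferroni-corrected minimum of the single-trait P-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import kernels as _kern
from .kernels import DEFAULT_GRID
from .quadform import quadform_pvalue
from .sumstats import LDMatrix, ScoreStats
from .trait_cov import JointStats, TraitCovariance, assemble_joint

log = logging.getLogger(__name__)

__all__ = [
    "GeneTestResult",
    "q_rho_test",
    "cauchy_combine",
    "cauchy_statistic",
    "mtar_grid_test",
    "single_trait_tests",
    "omnibus",
    "mtar_gene_test",
]

# guard for tan((0.5 - p) * pi) overflow in double precision
_SMALL_P = 1e-16
_P_ONE_CLAMP = 1.0 - 1e-16
_LARGE_T = 1e15


def _tangents(pvalues, clamp_one: bool = True) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if np.any(~np.isfinite(p) | (p <= 0.0) | (p > 1.0)):
        raise ValueError("P-values must lie in (0, 1] for Cauchy combination")
    if clamp_one:
        p = np.minimum(p, _P_ONE_CLAMP)
    out = np.empty_like(p)
    small = p < _SMALL_P
    # asymptotic identity tan((0.5 - p) pi) -> 1 / (p pi) as p -> 0
    out[small] = 1.0 / (p[small] * math.pi)
    out[~small] = np.tan((0.5 - p[~small]) * math.pi)
    return out


def _cauchy_sf(t: float) -> float:
    if t > _LARGE_T:
        return 1.0 / (math.pi * t)
    return 0.5 - math.atan(t) / math.pi


def cauchy_statistic(pvalues, weights=None) -> float:
    """(Weighted) mean of tan{(0.5 - p_i) pi} over the input P-values."""
    t = _tangents(pvalues)
    if weights is None:
        return float(np.mean(t))
    w = np.asarray(weights, dtype=float)
    if w.size != t.size or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and sum to > 0")
    return float(np.sum(w * t) / w.sum())


def cauchy_combine(pvalues, weights=None) -> float:
    """Cauchy combination of dependent P-values.

    The combined P-value is 0.5 - arctan(T)/pi where T is the mean tangent;
    under the null each tangent is standard Cauchy, and so is their mean.
    """
    return _cauchy_sf(cauchy_statistic(pvalues, weights))


def _present_mask(joint: JointStats) -> np.ndarray | None:
    """Global indices of (trait, variant) pairs present in the stacked beta.

    Variants monomorphic in some trait are handled by deleting their rows
    and columns from that trait's block of beta, Sigma, and B. Cached on
    the JointStats (the index structure is immutable once assembled).
    """
    if "_present_mask" in joint.field_notes:
        return joint.field_notes["_present_mask"]
    m = joint.n_variants
    if all(ix.size == m and np.array_equal(ix, np.arange(m))
           for ix in joint.variant_index):
        mask = None
    else:
        mask = np.concatenate([k * m + ix
                               for k, ix in enumerate(joint.variant_index)])
    joint.field_notes["_present_mask"] = mask
    return mask


def _factor_sigma(sigma: np.ndarray):
    """Cholesky factor of Sigma, adding a ridge when not positive definite."""
    ridge_count = 0
    ridge = 1e-10 * float(np.mean(np.diag(sigma))) or 1e-10
    for _ in range(12):
        try:
            chol = linalg.cho_factor(sigma, lower=True)
            return chol, ridge_count
        except np.linalg.LinAlgError:
            sigma = sigma + ridge * np.eye(sigma.shape[0])
            ridge *= 10.0
            ridge_count += 1
    raise np.linalg.LinAlgError("Sigma could not be factorised")


def q_rho_test(joint: JointStats, kernel, acc: float = 1e-9,
               _chol=None, _linv=None, _z=None):
    """Q_rho = beta_hat' Sigma^{-1} B Sigma^{-1} beta_hat and its P-value.

    ``kernel`` is a KernelSpec or a dense B matrix on the full (union)
    trait-major layout. The null eigenvalues are those of Sigma^{-1} B,
    computed from the symmetrised congruence L^{-1} B L^{-T}.
    """
    b = kernel.B if isinstance(kernel, _kern.KernelSpec) else np.asarray(
        kernel, dtype=float)
    mask = _present_mask(joint)
    if mask is not None:
        b = b[np.ix_(mask, mask)]
    n = joint.beta.size
    if b.shape != (n, n):
        raise ValueError(f"kernel dimension {b.shape} does not match stacked "
                         f"effects ({n})")
    if _chol is None:
        _chol, _ = _factor_sigma(joint.sigma)
    z = linalg.cho_solve(_chol, joint.beta) if _z is None else _z
    q = float(z @ b @ z)
    if _linv is None:
        _linv = linalg.solve_triangular(_chol[0], np.eye(n), lower=True)
    lam = None
    if (isinstance(kernel, _kern.KernelSpec) and kernel.rho1 == 1.0
            and mask is None):
        # burden limit: B1 = w w', so B = M B2 M' with M = I_K (x) w and the
        # nonzero null eigenvalues are those of (L^-1 M)'(L^-1 M) B2
        K = kernel.n_traits
        m = kernel.n_variants
        M = np.zeros((n, K))
        for k in range(K):
            M[k * m:(k + 1) * m, k] = kernel.weights
        A = _linv @ M
        S = A.T @ A
        try:
            ls = np.linalg.cholesky(S)
            lam = np.linalg.eigvalsh(ls.T @ kernel.B2 @ ls)
        except np.linalg.LinAlgError:
            lam = None
    if lam is None:
        lam = np.linalg.eigvalsh(_linv @ b @ _linv.T)
    res = quadform_pvalue(q, lam, acc=acc)
    return q, res.p, res


@dataclass
class GeneTestResult:
    """All per-gene P-values and diagnostics."""

    gene: str
    traits: list[str]
    n_variants: int
    p_mtar_o: float
    p_cmtar: float
    p_imtar: float
    p_cctp: float
    p_minp: float
    q_mtar_o: float
    q_cmtar: float
    q_imtar: float
    q_cctp: float
    p_skat: np.ndarray
    p_burden: np.ndarray
    per_point: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def mtar_grid_test(joint: JointStats, structure: str, C, weights,
                   grid=DEFAULT_GRID, indicators=None, acc: float = 1e-9,
                   _chol=None, _linv=None, _kernels=None, _z=None,
                   _shared=None):
    """Cauchy-combined variance-component test over the (rho1, rho2) grid.

    Returns (T, p, per_point) where per_point maps (rho1, rho2) to
    (Q_rho, p_rho, method). Grid points where the P-value computation fails
    are dropped with a warning and the combination size adjusted.
    """
    points = _kern.grid_points(grid)
    if not points:
        raise ValueError("grid must be nonempty")
    if _chol is None:
        _chol, _ = _factor_sigma(joint.sigma)
    if _linv is None:
        n = joint.beta.size
        _linv = linalg.solve_triangular(_chol[0], np.eye(n), lower=True)
    per_point = {}
    pvals = []
    for rho1, rho2 in points:
        try:
            # at rho2 = 1 both structures give Omega2 = C: share the result
            if _shared is not None and rho2 == 1.0 and \
                    (rho1, rho2) in _shared:
                q, p, res = _shared[(rho1, rho2)]
                per_point[(rho1, rho2)] = (q, p, res.method)
                pvals.append(p)
                continue
            key = (structure, rho1, rho2)
            if _kernels is not None and key in _kernels:
                spec = _kernels[key]
            else:
                spec = _kern.build_effect_kernel(rho1, rho2, structure,
                                                 weights=weights, C=C,
                                                 indicators=indicators)
                if _kernels is not None:
                    _kernels[key] = spec
            q, p, res = q_rho_test(joint, spec, acc=acc, _chol=_chol,
                                   _linv=_linv, _z=_z)
            if _shared is not None and rho2 == 1.0:
                _shared[(rho1, rho2)] = (q, p, res)
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("grid point (%.2g, %.2g) dropped: %s",
                        rho1, rho2, exc)
            continue
        per_point[(rho1, rho2)] = (q, p, res.method)
        pvals.append(p)
    if not pvals:
        raise ValueError("all grid points failed")
    t = cauchy_statistic(pvals)
    return t, _cauchy_sf(t), per_point


def single_trait_tests(stats: list[ScoreStats], weights_by_trait,
                       acc: float = 1e-9):
    """Per-trait SKAT and burden tests and the cctP combination.

    SKAT: Q = sum_j w_j^2 U_j^2 with null weights eig(W V W). Burden:
    two-sided normal test of w'U with variance w'Vw (P-value 1, flagged,
    when the burden variance is zero). Q_cctP averages the tangents of the
    2K P-values; its P-value is 0.5 - arctan(Q_cctP)/pi.
    """
    p_skat, p_burden, flags = [], [], []
    for st, w in zip(stats, weights_by_trait):
        w = np.asarray(w, dtype=float)
        wu = w * st.U
        q_skat = float(wu @ wu)
        lam = np.linalg.eigvalsh(st.V * np.outer(w, w))
        res = quadform_pvalue(q_skat, lam, acc=acc)
        p_skat.append(res.p)
        var_b = float(w @ st.V @ w)
        if var_b <= 0:
            p_burden.append(1.0)
            flags.append("zero_burden_variance")
        else:
            z2 = float(w @ st.U) ** 2 / var_b
            p_burden.append(math.erfc(math.sqrt(0.5 * z2)))
            flags.append(res.method)
    ps = np.asarray(p_skat + p_burden)
    q_cctp = cauchy_statistic(ps)
    return (np.asarray(p_skat), np.asarray(p_burden), q_cctp,
            _cauchy_sf(q_cctp), flags)


def omnibus(p_cmtar: float, p_imtar: float, p_cctp: float,
            single_trait_pvalues):
    """MTAR-O Cauchy combination and the Bonferroni minimum P-value.

    minP multiplies the smallest of the 2K single-trait P-values (SKAT and
    burden per trait) by 2K, capped at 1.
    """
    for name, p in (("cMTAR", p_cmtar), ("iMTAR", p_imtar),
                    ("cctP", p_cctp)):
        if p is None or not 0.0 < p <= 1.0:
            raise ValueError(f"component P-value for {name} missing or "
                             "outside (0, 1]")
    q_o = cauchy_statistic([p_cmtar, p_imtar, p_cctp])
    sp = np.asarray(single_trait_pvalues, dtype=float)
    minp = min(1.0, float(sp.min()) * sp.size)
    return q_o, _cauchy_sf(q_o), minp


def mtar_gene_test(stats: list[ScoreStats], ld: LDMatrix,
                   zeta: TraitCovariance | np.ndarray, C=None,
                   weight_scheme: str = "beta_1_25", grid=DEFAULT_GRID,
                   indicators=None, acc: float = 1e-9,
                   joint: JointStats | None = None,
                   _kernels=None) -> GeneTestResult:
    """Run the full battery (iMTAR, cMTAR, cctP, minP, MTAR-O) on one gene."""
    if joint is None:
        joint = assemble_joint(stats, zeta, ld)
    K = joint.n_traits
    if C is None:
        C = np.eye(K)
    maf = joint.maf
    if np.any(np.isnan(maf)):
        raise ValueError("missing MAF for some union variants")
    weights = _kern.variant_weights(maf, weight_scheme)
    chol, n_ridge = _factor_sigma(joint.sigma)
    n = joint.beta.size
    linv = linalg.solve_triangular(chol[0], np.eye(n), lower=True)
    z = linv.T @ (linv @ joint.beta)
    shared: dict = {}

    t_i, p_i, pts_i = mtar_grid_test(joint, "iMTAR", C, weights, grid,
                                     indicators, acc, _chol=chol, _linv=linv,
                                     _kernels=_kernels, _z=z, _shared=shared)
    t_c, p_c, pts_c = mtar_grid_test(joint, "cMTAR", C, weights, grid,
                                     indicators, acc, _chol=chol, _linv=linv,
                                     _kernels=_kernels, _z=z, _shared=shared)
    weights_by_trait = [weights[ix] for ix in joint.variant_index]
    p_skat, p_burden, q_cctp, p_cctp, st_flags = single_trait_tests(
        stats, weights_by_trait, acc=acc)
    q_o, p_o, minp = omnibus(p_c, p_i, p_cctp,
                             np.concatenate([p_skat, p_burden]))
    per_point = {("iMTAR",) + k: v for k, v in pts_i.items()}
    per_point.update({("cMTAR",) + k: v for k, v in pts_c.items()})
    diagnostics = {
        "sigma_ridge_steps": n_ridge,
        "grid_size": len(_kern.grid_points(grid)),
        "grid_points_used": (len(pts_i), len(pts_c)),
        "single_trait_methods": st_flags,
        "methods": sorted({v[2] for v in per_point.values()}),
    }
    return GeneTestResult(
        gene=stats[0].gene, traits=joint.traits, n_variants=joint.n_variants,
        p_mtar_o=p_o, p_cmtar=p_c, p_imtar=p_i, p_cctp=p_cctp, p_minp=minp,
        q_mtar_o=q_o, q_cmtar=t_c, q_imtar=t_i, q_cctp=q_cctp,
        p_skat=p_skat, p_burden=p_burden, per_point=per_point,
        diagnostics=diagnostics)
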