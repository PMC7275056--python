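"""Batched test battery for simulation studies.

Computes the full battery (per-grid-point variance-component tests, their
Cauchy combinations, single-trait SKAT/burden, cctP, minP, MTAR-O) for many
replicates that share a gene region, using stacked linear algebra and the
compiled tail-probability kernels. Produces the same P-values as
``gene_tests.mtar_gene_test`` (verified by an equivalence test); exists
because calibration studies run 10^5 replicates.
"""

from __future__ import annotations

import math

import numpy as np

from . import _qfcompiled, kernels as _kern
from .quadform import EIG_REL_TOL, quadform_pvalue
from .trait_cov import _inv_with_ridge

try:
    from numba import njit

    HAVE_NUMBA = _qfcompiled.HAVE_NUMBA
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
    njit = _qfcompiled.njit

_P_ONE = 1.0 - 1e-16


@njit(cache=True)
def _pvals_batch_nb(qs, lams, acc):
    """Tail probabilities for many (q, lam-row) pairs.

    Returns p-values with -1 flagging rows that need the python fallback
    (Liu moment matching or an equal-weight chi-square with r > 2).
    """
    n = qs.shape[0]
    out = np.empty(n)
    for i in range(n):
        lam_raw = lams[i]
        lmax = 0.0
        for j in range(lam_raw.shape[0]):
            if lam_raw[j] > lmax:
                lmax = lam_raw[j]
        if lmax <= 0.0:
            out[i] = 1.0
            continue
        cnt = 0
        for j in range(lam_raw.shape[0]):
            if lam_raw[j] > EIG_REL_TOL * lmax:
                cnt += 1
        lam = np.empty(cnt)
        k = 0
        lmin = lmax
        for j in range(lam_raw.shape[0]):
            if lam_raw[j] > EIG_REL_TOL * lmax:
                lam[k] = lam_raw[j]
                if lam_raw[j] < lmin:
                    lmin = lam_raw[j]
                k += 1
        q = qs[i]
        if q <= 0.0:
            out[i] = 1.0
            continue
        if lmax - lmin <= 1e-12 * lmax:
            lbar = 0.5 * (lmax + lmin)
            if cnt == 1:
                out[i] = math.erfc(math.sqrt(0.5 * q / lbar))
                continue
            if cnt == 2:
                out[i] = math.exp(-0.5 * q / lbar)
                continue
            out[i] = -1.0  # python: exact chi-square, r > 2
            continue
        p = _qfcompiled.cf_inversion_nb(q, lam, acc, 1 << 23)
        if p >= 50.0 * acc and p <= 1.0:
            out[i] = p
            continue
        p_sp = _qfcompiled.saddlepoint_nb(q, lam)
        if 0.0 < p_sp < 1.0:
            out[i] = p_sp
            continue
        if 0.0 < p <= 1.0:
            out[i] = p
            continue
        out[i] = -1.0  # python: Liu fallback
    return out


def _pvals_batch(qs, lams, acc):
    qs = np.ascontiguousarray(qs, dtype=float)
    lams = np.ascontiguousarray(lams, dtype=float)
    out = _pvals_batch_nb(qs, lams, acc)
    bad = np.flatnonzero(out < 0.0)
    for i in bad:
        out[i] = quadform_pvalue(qs[i], lams[i], acc=acc).p
    return out


def _cauchy_rows(pmat):
    """Row-wise Cauchy combination of a (B, n_tests) P-value matrix."""
    p = np.clip(pmat, 5e-324, _P_ONE)
    t = np.where(p < 1e-16, 1.0 / (p * math.pi),
                 np.tan((0.5 - p) * math.pi))
    tbar = t.mean(axis=1)
    out = 0.5 - np.arctan(tbar) / math.pi
    big = tbar > 1e15
    out[big] = 1.0 / (math.pi * tbar[big])
    return out


def _stacked_inv(v):
    """Stacked matrix inverse with per-item ridge fallback."""
    try:
        inv = np.linalg.inv(v)
        if np.isfinite(inv).all():
            return inv
    except np.linalg.LinAlgError:
        pass
    out = np.empty_like(v)
    for i in range(v.shape[0]):
        out[i] = _inv_with_ridge(v[i], {})
    return out


def battery_batch(U, V, zeta, R, C, weights, grid=_kern.DEFAULT_GRID,
                  acc: float = 1e-6):
    """Full battery for B replicates sharing a gene region.

    U: (B, K, m) score vectors; V: (B, K, m, m) covariances; zeta: (K, K);
    R: (m, m) LD; C: (K, K) genetic correlations; weights: (m,).
    Returns a dict of length-B P-value arrays keyed MTAR-O / cMTAR / iMTAR /
    cctP / minP.
    """
    U = np.asarray(U, float)
    V = np.asarray(V, float)
    B_rep, K, m = U.shape
    n = K * m
    w = np.asarray(weights, float)

    vinv = _stacked_inv(V.reshape(B_rep * K, m, m)).reshape(B_rep, K, m, m)
    beta = np.einsum("bkmn,bkn->bkm", vinv, U).reshape(B_rep, n)
    dhalf = np.sqrt(np.clip(np.einsum("bkmm->bkm", V), 0.0, None))

    sigma = np.zeros((B_rep, n, n))
    for k in range(K):
        sk = slice(k * m, (k + 1) * m)
        sigma[:, sk, sk] = vinv[:, k]
        for kp in range(k + 1, K):
            if zeta[k, kp] == 0.0:
                continue
            skp = slice(kp * m, (kp + 1) * m)
            mid = R[None, :, :] * dhalf[:, k, :, None] * dhalf[:, kp, None, :]
            blk = zeta[k, kp] * (vinv[:, k] @ mid @ vinv[:, kp])
            sigma[:, sk, skp] = blk
            sigma[:, skp, sk] = np.swapaxes(blk, 1, 2)

    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # indefinite Sigma for some replicate (e.g. near-singular V):
        # repair exactly as the per-gene path does — eigenvalue clipping
        # followed by an escalating ridge if still not factorisable
        from .gene_tests import _factor_sigma
        from .trait_cov import repair_psd

        L = np.empty_like(sigma)
        for i in range(B_rep):
            try:
                L[i] = np.linalg.cholesky(sigma[i])
            except np.linalg.LinAlgError:
                chol, _ = _factor_sigma(repair_psd(sigma[i]))
                L[i] = np.tril(chol[0])
    Li = np.linalg.inv(L)
    lib = np.einsum("bij,bj->bi", Li, beta)
    z = np.einsum("bji,bj->bi", Li, lib)  # Sigma^-1 beta

    points = _kern.grid_points(grid)
    structures = ("iMTAR", "cMTAR")
    # build kernels once; share rho2 = 1 between structures
    specs = {}
    for structure in structures:
        for rho1, rho2 in points:
            key = ("iMTAR", rho1, rho2) if rho2 == 1.0 \
                else (structure, rho1, rho2)
            if key not in specs:
                specs[key] = _kern.build_effect_kernel(
                    rho1, rho2, key[0], weights=w, C=C)

    point_p = {}
    for key, spec in specs.items():
        bz = z @ spec.B  # (B, n)
        q = np.einsum("bi,bi->b", bz, z)
        lam = None
        if spec.rho1 == 1.0:
            # burden limit: rank-K kernel, eigenvalues from a K x K matrix
            M = np.zeros((n, K))
            for k in range(K):
                M[k * m:(k + 1) * m, k] = w
            A = Li @ M  # (B, n, K)
            S = np.swapaxes(A, 1, 2) @ A
            try:
                ls = np.linalg.cholesky(S)
                small = np.swapaxes(ls, 1, 2) @ spec.B2 @ ls
                lam = np.linalg.eigvalsh(small)
            except np.linalg.LinAlgError:
                lam = None  # degenerate weights: use the full-size route
        if lam is None:
            S = Li @ spec.B @ np.swapaxes(Li, 1, 2)
            lam = np.linalg.eigvalsh(S)
        lam = np.clip(lam, 0.0, None)
        point_p[key] = _pvals_batch(q, lam, acc)

    def point(structure, rho1, rho2):
        key = ("iMTAR", rho1, rho2) if rho2 == 1.0 \
            else (structure, rho1, rho2)
        return point_p[key]

    p_imtar = _cauchy_rows(np.column_stack(
        [point("iMTAR", r1, r2) for r1, r2 in points]))
    p_cmtar = _cauchy_rows(np.column_stack(
        [point("cMTAR", r1, r2) for r1, r2 in points]))

    # single-trait SKAT and burden
    wu = U * w[None, None, :]
    q_skat = np.einsum("bkm,bkm->bk", wu, wu)
    wvw = V * np.outer(w, w)[None, None, :, :]
    lam_st = np.clip(np.linalg.eigvalsh(
        wvw.reshape(B_rep * K, m, m)), 0.0, None)
    p_skat = _pvals_batch(q_skat.reshape(-1), lam_st,
                          acc).reshape(B_rep, K)
    score_b = np.einsum("bkm,m->bk", U, w)
    var_b = np.einsum("m,bkmn,n->bk", w, V, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(var_b > 0, score_b**2 / np.where(var_b > 0, var_b, 1.0),
                      0.0)
    from scipy.special import erfc
    p_burden = np.where(var_b > 0, erfc(np.sqrt(0.5 * z2)), 1.0)

    st = np.concatenate([p_skat, p_burden], axis=1)
    p_cctp = _cauchy_rows(st)
    p_minp = np.minimum(1.0, st.min(axis=1) * st.shape[1])
    p_omni = _cauchy_rows(np.column_stack([p_cmtar, p_imtar, p_cctp]))
    return {"MTAR-O": p_omni, "cMTAR": p_cmtar, "iMTAR": p_imtar,
            "cctP": p_cctp, "minP": p_minp}


def cohort_scores_batch(Y, X1, X2, G, gram):
    """Gaussian score statistics for B phenotype replicates on one cohort.

    Y: (B, n, K) phenotypes (NaN columns allowed, caller masks);
    X1, X2: (B, n) covariates; G: (n, m). Returns U: (B, K, m),
    V: (B, K, m, m).
    """
    B_rep, n_sub, K = Y.shape
    m = G.shape[1]
    ones = np.ones((B_rep, n_sub))
    X = np.stack([ones, X1, X2], axis=2)  # (B, n, 3)
    xt = np.swapaxes(X, 1, 2)
    xtx = xt @ X
    xty = xt @ Y
    gamma = np.linalg.solve(xtx, xty)  # (B, 3, K)
    resid = Y - X @ gamma
    a = np.einsum("bnk,bnk->bk", resid, resid) / n_sub  # (B, K)
    # U = G' resid / a
    u = np.swapaxes(G.T @ resid, 1, 2) / a[:, :, None]
    gtx = G.T @ X  # (B, m, 3)
    corr = gtx @ np.linalg.inv(xtx) @ np.swapaxes(gtx, 1, 2)
    v = (gram[None, :, :] - corr)[:, None, :, :] / a[:, :, None, None]
    return u, v
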