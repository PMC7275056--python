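"""Tail probabilities for quadratic forms in normal variables.

A variance-component score statistic Q = sum_i lambda_i * chi^2_1 follows a
mixture of chi-square distribution under the null. The survival function
P(Q > q) is computed by numerical inversion of the characteristic function
(the approach of Davies), with a saddlepoint approximation (Kuonen) for the
far tail and a moment-matched noncentral chi-square (Liu et al.) as a last
resort. The method actually used is recorded on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import _qfcompiled

__all__ = ["QuadFormNull", "QuadFormPValue", "quadform_pvalue"]

# relative cutoff below which eigenvalues are treated as exact zeros
EIG_REL_TOL = 1e-10


@dataclass
class QuadFormNull:
    """Eigenvalue weights of the null mixture-of-chi-square distribution."""

    lam: np.ndarray
    method: str = "davies"

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float).ravel()
        if lam.size:
            lmax = float(np.max(np.abs(lam)))
            # negative numerical noise and near-zero weights drop together
            lam = lam[lam > EIG_REL_TOL * lmax] if lmax > 0 else lam[:0]
        self.lam = lam


@dataclass
class QuadFormPValue:
    p: float
    method: str
    degenerate: bool = False
    details: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.p


def _cumulant(lam: np.ndarray, s: np.ndarray) -> np.ndarray:
    """K(s) = -0.5 * sum log(1 - 2 s lam), the CGF of the mixture."""
    return -0.5 * np.sum(np.log1p(-2.0 * np.outer(s, lam)), axis=1)


# fractions of the CGF pole 1/(2 lam_max) probed by the Chernoff bound
_S_FRACTIONS = 1.0 - np.geomspace(1e-6, 0.9999, 48)

# candidate truncation cuts, as multiples of the node spacing delta
_U_RATIOS = np.geomspace(4.0, 4.0 * (1 << 23), 96)


def _chernoff_point(lam: np.ndarray, eps: float, q: float) -> float:
    """Smallest x with the Chernoff bound P(Q > x) <= eps.

    exp(K(s) - s x) <= eps iff x >= (K(s) - log eps) / s, so the tightest
    point is the minimum of that expression over s in (0, 1/(2 lam_max)).
    """
    s = (0.5 / lam.max()) * _S_FRACTIONS
    ks = _cumulant(lam, s)
    x = float(np.min((ks - math.log(eps)) / s))
    return max(x, q, 1e-8)


def _cf_inversion(q: float, lam: np.ndarray, acc: float,
                  max_nodes: int = 1 << 23) -> float | None:
    """Midpoint-rule inversion of the characteristic function.

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * gamma(u)) du with
    theta(u) = 0.5 * sum_j arctan(lam_j u) - 0.5 q u and
    gamma(u) = prod_j (1 + lam_j^2 u^2)^(1/4).

    The midpoint sum with spacing delta has aliasing error bounded by the
    distribution tail beyond q + 2*pi/delta (controlled by a Chernoff bound).
    The series is truncated at U where either the integrand envelope bound
    or the remainder of a two-term integration-by-parts expansion of the
    tail integral drops below acc; in the latter case the expansion itself
    is added as an analytic tail correction, which keeps the node count
    small even for slowly decaying (small-rank) spectra. Returns None when
    the required number of nodes exceeds ``max_nodes``.
    """
    scale = float(lam.max())
    lam = lam / scale
    q = q / scale
    r = lam.size

    x_big = _chernoff_point(lam, acc / 10.0, q)
    period = q + x_big
    delta = 2.0 * math.pi / period

    # envelope e(u) = 1 / (u * gamma(u)) <= C * u^(-1 - r/2),
    # log C = -0.5 * sum log lam
    log_c = -0.5 * float(np.sum(np.log(lam)))
    tol = acc / 4.0
    lam2 = lam**2
    # truncation search vectorised over a geometric grid of candidate cuts
    u_grid = delta * _U_RATIOS[_U_RATIOS <= 4.0 * max_nodes]
    lu2 = (u_grid[:, None] * lam[None, :]) ** 2
    int_tail = np.exp(log_c + math.log(2.0 / r)
                      - 0.5 * r * np.log(u_grid))
    e_u = np.exp(-0.25 * np.sum(np.log1p(lu2), axis=1)) / u_grid
    th1 = 0.5 * np.sum(lam[None, :] / (1.0 + lu2), axis=1) - 0.5 * q
    with np.errstate(divide="ignore", invalid="ignore"):
        th2 = -np.sum(lam[None, :] ** 3 * u_grid[:, None] / (1.0 + lu2) ** 2,
                      axis=1)
        e1 = e_u * (-1.0 / u_grid
                    - 0.5 * np.sum(lam2[None, :] * u_grid[:, None]
                                   / (1.0 + lu2), axis=1))
        h = e1 / th1 - e_u * th2 / th1**2
        rem = 4.0 * np.abs(h / th1) / math.pi
    ok_osc = (q > 0) & (th1 < -0.25 * q)  # past the stationary-phase point
    rem = np.where(ok_osc, rem, np.inf)
    ok = (rem <= tol) | (int_tail <= tol)
    if not np.any(ok):
        return None
    idx = int(np.argmax(ok))
    u_hi = float(u_grid[idx])
    tail = True if (rem[idx] <= tol) else None
    n_nodes = int(math.ceil(u_hi / delta))
    if n_nodes > max_nodes:
        return None

    total = 0.0
    chunk = 1 << 15
    u_hi = n_nodes * delta  # recompute the correction at the exact cut
    if tail is not None:
        lu2 = lam2 * u_hi**2
        th1 = 0.5 * float(np.sum(lam / (1.0 + lu2))) - 0.5 * q
        theta = 0.5 * float(np.sum(np.arctan(lam * u_hi))) - 0.5 * q * u_hi
        e_u = math.exp(-0.25 * float(np.sum(np.log1p(lu2)))) / u_hi
        th2 = -float(np.sum(lam**3 * u_hi / (1.0 + lu2) ** 2))
        e1 = e_u * (-1.0 / u_hi
                    - 0.5 * float(np.sum(lam2 * u_hi / (1.0 + lu2))))
        h = e1 / th1 - e_u * th2 / th1**2
        tail = (math.cos(theta) * e_u / th1
                - math.sin(theta) * h / th1) / math.pi
    for start in range(0, n_nodes, chunk):
        u = (np.arange(start, min(start + chunk, n_nodes)) + 0.5) * delta
        uu = u[:, None] * lam[None, :]
        theta = 0.5 * np.sum(np.arctan(uu), axis=1) - 0.5 * q * u
        log_gamma = 0.25 * np.sum(np.log1p(uu**2), axis=1)
        total += float(np.sum(np.sin(theta) * np.exp(-log_gamma) / u))
    return 0.5 + (delta / math.pi) * total + (tail or 0.0)


def saddlepoint_pvalue(q: float, lam: np.ndarray) -> float | None:
    """Lugannani-Rice / Kuonen saddlepoint tail approximation."""
    lmax = float(lam.max())
    mean = float(lam.sum())
    if abs(q - mean) < 1e-12 * max(mean, 1.0):
        return None

    def kprime(s: float) -> float:
        return float(np.sum(lam / (1.0 - 2.0 * s * lam)))

    upper = 0.5 / lmax
    if q > mean:
        lo, hi = 0.0, upper * (1.0 - 1e-12)
        while kprime(hi) < q:
            hi = upper - (upper - hi) * 0.1
            if upper - hi < 1e-300:
                return None
    else:
        lo = -1.0 / lmax
        while kprime(lo) > q:
            lo *= 2.0
            if not math.isfinite(lo):
                return None
        hi = 0.0
    try:
        s_hat = optimize.brentq(lambda s: kprime(s) - q, lo, hi, xtol=1e-14)
    except ValueError:
        return None
    k0 = -0.5 * float(np.sum(np.log1p(-2.0 * s_hat * lam)))
    k2 = 2.0 * float(np.sum(lam**2 / (1.0 - 2.0 * s_hat * lam) ** 2))
    arg = 2.0 * (s_hat * q - k0)
    if arg <= 0 or k2 <= 0:
        return None
    w = math.copysign(math.sqrt(arg), s_hat)
    v = s_hat * math.sqrt(k2)
    if abs(w) < 1e-8 or v == 0:
        return None
    return float(stats.norm.sf(w + math.log(v / w) / w))


def liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched noncentral chi-square approximation."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2.0 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
        a = math.sqrt(dof)
    mu_q = c1
    sigma_q = math.sqrt(2.0 * c2)
    mu_x = dof + delta
    sigma_x = math.sqrt(2.0 * (dof + 2.0 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, dof, delta)) if delta > 0 else float(
        stats.chi2.sf(t, dof))


def quadform_pvalue(q: float, lam, acc: float = 1e-9) -> QuadFormPValue:
    """P(sum_i lam_i chi^2_1 > q) with automatic method fallback.

    Parameters
    ----------
    q : observed statistic.
    lam : eigenvalues of the null mixture (negatives within numerical
        tolerance are clipped; zeros dropped).
    acc : absolute accuracy target of the inversion step.
    """
    null = QuadFormNull(np.asarray(lam, dtype=float))
    lam = null.lam
    if lam.size == 0:
        return QuadFormPValue(1.0, "degenerate", degenerate=True)
    q = float(q)
    if q <= 0.0:
        return QuadFormPValue(1.0, "degenerate" if q < 0 else "exact",
                              degenerate=q < 0)
    lmin, lmax = float(lam.min()), float(lam.max())
    if lmax - lmin <= 1e-12 * lmax:
        # equal weights: exact scaled chi-square
        lbar = 0.5 * (lmax + lmin)
        if lam.size == 1:
            p = math.erfc(math.sqrt(0.5 * q / lbar))
        elif lam.size == 2:
            p = math.exp(-0.5 * q / lbar)
        else:
            p = float(stats.chi2.sf(q / lbar, lam.size))
        return QuadFormPValue(p, "exact_chisq")

    if _qfcompiled.HAVE_NUMBA:
        p = _qfcompiled.cf_inversion_nb(q, lam, acc, 1 << 23)
        if p < 0.0:
            p = None
    else:
        p = _cf_inversion(q, lam, acc)
    if p is not None and 50.0 * acc <= p <= 1.0:
        return QuadFormPValue(min(p, 1.0), "davies")
    # far tail (or inversion gave up): saddlepoint has good relative accuracy
    if _qfcompiled.HAVE_NUMBA:
        p_sp = _qfcompiled.saddlepoint_nb(q, lam)
        if p_sp < 0.0:
            p_sp = None
    else:
        p_sp = saddlepoint_pvalue(q, lam)
    if p_sp is not None and 0.0 < p_sp < 1.0:
        return QuadFormPValue(p_sp, "saddlepoint")
    if p is not None and 0.0 < p <= 1.0:
        return QuadFormPValue(p, "davies")
    return QuadFormPValue(min(max(liu_pvalue(q, lam), 5e-324), 1.0), "liu")
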