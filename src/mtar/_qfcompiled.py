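"""Compiled (numba) kernels for the mixture-of-chi-square machinery.

Implements the same characteristic-function inversion and saddlepoint
computations as `quadform` in nopython mode; `quadform` falls back to its
pure-numpy implementations when numba is unavailable. Simulation studies
make millions of tail-probability calls, which is what makes compilation
worthwhile.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# fractions of the CGF pole probed by the Chernoff bound (see quadform)
S_FRACTIONS = 1.0 - np.geomspace(1e-6, 0.9999, 48)
# candidate truncation cuts as multiples of the node spacing
U_RATIOS = np.geomspace(4.0, 4.0 * (1 << 23), 96)


@njit(cache=True)
def _chernoff_point_nb(lam, eps, q):
    lmax = lam.max()
    log_eps = math.log(eps)
    best = np.inf
    for i in range(S_FRACTIONS.size):
        s = 0.5 / lmax * S_FRACTIONS[i]
        ks = 0.0
        for j in range(lam.size):
            ks += math.log1p(-2.0 * s * lam[j])
        ks *= -0.5
        x = (ks - log_eps) / s
        if x < best:
            best = x
    if best < q:
        best = q
    if best < 1e-8:
        best = 1e-8
    return best


@njit(cache=True)
def cf_inversion_nb(q, lam, acc, max_nodes):
    """Midpoint CF inversion with analytic tail correction.

    Mirrors quadform._cf_inversion; returns -1.0 when the node budget is
    exceeded (caller falls back).
    """
    scale = lam.max()
    lamn = lam / scale
    qn = q / scale
    r = lamn.size

    x_big = _chernoff_point_nb(lamn, acc / 10.0, qn)
    delta = 2.0 * math.pi / (qn + x_big)

    log_c = 0.0
    for j in range(r):
        log_c += math.log(lamn[j])
    log_c *= -0.5
    tol = acc / 4.0

    u_hi = -1.0
    use_tail = False
    for gi in range(U_RATIOS.size):
        u = delta * U_RATIOS[gi]
        if u / delta > 4.0 * max_nodes:
            break
        int_tail = math.exp(log_c + math.log(2.0 / r) - 0.5 * r * math.log(u))
        s_env = 0.0
        s_th1 = 0.0
        for j in range(r):
            lu2 = (lamn[j] * u) ** 2
            s_env += math.log1p(lu2)
            s_th1 += lamn[j] / (1.0 + lu2)
        e_u = math.exp(-0.25 * s_env) / u
        th1 = 0.5 * s_th1 - 0.5 * qn
        ok = False
        if qn > 0.0 and th1 < -0.25 * qn:
            s_th2 = 0.0
            s_e1 = 0.0
            for j in range(r):
                lu2 = (lamn[j] * u) ** 2
                s_th2 += lamn[j] ** 3 * u / (1.0 + lu2) ** 2
                s_e1 += lamn[j] ** 2 * u / (1.0 + lu2)
            th2 = -s_th2
            e1 = e_u * (-1.0 / u - 0.5 * s_e1)
            h = e1 / th1 - e_u * th2 / th1 ** 2
            rem = 4.0 * abs(h / th1) / math.pi
            if rem <= tol:
                ok = True
                use_tail = True
        if not ok and int_tail <= tol:
            ok = True
            use_tail = False
        if ok:
            u_hi = u
            break
    if u_hi < 0.0:
        return -1.0
    n_nodes = int(math.ceil(u_hi / delta))
    if n_nodes > max_nodes:
        return -1.0

    u_hi = n_nodes * delta
    tail = 0.0
    if use_tail:
        s_env = 0.0
        s_th1 = 0.0
        s_th2 = 0.0
        s_e1 = 0.0
        theta = 0.0
        for j in range(r):
            lu = lamn[j] * u_hi
            lu2 = lu * lu
            s_env += math.log1p(lu2)
            s_th1 += lamn[j] / (1.0 + lu2)
            s_th2 += lamn[j] ** 3 * u_hi / (1.0 + lu2) ** 2
            s_e1 += lamn[j] ** 2 * u_hi / (1.0 + lu2)
            theta += math.atan(lu)
        theta = 0.5 * theta - 0.5 * qn * u_hi
        e_u = math.exp(-0.25 * s_env) / u_hi
        th1 = 0.5 * s_th1 - 0.5 * qn
        th2 = -s_th2
        e1 = e_u * (-1.0 / u_hi - 0.5 * s_e1)
        h = e1 / th1 - e_u * th2 / th1 ** 2
        tail = (math.cos(theta) * e_u / th1
                - math.sin(theta) * h / th1) / math.pi

    total = 0.0
    for k in range(n_nodes):
        u = (k + 0.5) * delta
        theta = 0.0
        log_gamma = 0.0
        for j in range(r):
            lu = lamn[j] * u
            theta += math.atan(lu)
            log_gamma += math.log1p(lu * lu)
        theta = 0.5 * theta - 0.5 * qn * u
        total += math.sin(theta) * math.exp(-0.25 * log_gamma) / u
    return 0.5 + (delta / math.pi) * total + tail


@njit(cache=True)
def saddlepoint_nb(q, lam):
    """Kuonen saddlepoint tail approximation; -1.0 on failure."""
    lmax = lam.max()
    mean = lam.sum()
    if abs(q - mean) < 1e-12 * max(mean, 1.0):
        return -1.0
    upper = 0.5 / lmax
    # bracket the saddlepoint of K'(s) = q
    if q > mean:
        lo = 0.0
        hi = upper * (1.0 - 1e-12)
        for _ in range(200):
            kp = 0.0
            for j in range(lam.size):
                kp += lam[j] / (1.0 - 2.0 * hi * lam[j])
            if kp >= q:
                break
            hi = upper - (upper - hi) * 0.1
            if upper - hi < 1e-300:
                return -1.0
    else:
        lo = -1.0 / lmax
        hi = 0.0
        for _ in range(200):
            kp = 0.0
            for j in range(lam.size):
                kp += lam[j] / (1.0 - 2.0 * lo * lam[j])
            if kp <= q:
                break
            lo *= 2.0
            if not math.isfinite(lo):
                return -1.0
    # bisection (robust; K' is monotone increasing)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        kp = 0.0
        for j in range(lam.size):
            kp += lam[j] / (1.0 - 2.0 * mid * lam[j])
        if kp < q:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(abs(hi), 1.0):
            break
    s_hat = 0.5 * (lo + hi)
    k0 = 0.0
    k2 = 0.0
    for j in range(lam.size):
        om = 1.0 - 2.0 * s_hat * lam[j]
        k0 += math.log(om)
        k2 += lam[j] ** 2 / om ** 2
    k0 *= -0.5
    k2 *= 2.0
    arg = 2.0 * (s_hat * q - k0)
    if arg <= 0.0 or k2 <= 0.0:
        return -1.0
    w = math.sqrt(arg)
    if s_hat < 0.0:
        w = -w
    v = s_hat * math.sqrt(k2)
    if abs(w) < 1e-8 or v == 0.0:
        return -1.0
    z = w + math.log(v / w) / w
    return 0.5 * math.erfc(z / math.sqrt(2.0))
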