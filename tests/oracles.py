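"""Independent oracles for mixture-of-chi-square tail probabilities.

These deliberately use different algorithms from the package (a series of
central chi-square CDFs, and recursive conditioning with adaptive
quadrature) so the implementation and its checks never share a code path.
"""

import numpy as np
from scipy import integrate, stats


def ruben_sf(q, lam, n_terms=400):
    """Ruben's series: P(sum lam_i chi2_1 > q) as a mixture of central
    chi-square CDFs with scale c = min(lam). Accurate when max(lam)/min(lam)
    is moderate (series ratio 1 - min/max)."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12 * lam.max()]
    c = lam.min()
    r = lam.size
    a = np.zeros(n_terms)
    a[0] = float(np.prod(np.sqrt(c / lam)))
    ratios = 1.0 - c / lam
    b = np.array([np.sum(ratios**k) for k in range(1, n_terms + 1)])
    for k in range(1, n_terms):
        a[k] = 0.5 / k * float(np.dot(b[:k][::-1], a[:k]))
    if a.sum() < 1.0 - 1e-10:
        raise ValueError("Ruben series not converged; increase n_terms")
    dfs = r + 2.0 * np.arange(n_terms)
    cdf = stats.chi2.cdf(q / c, dfs)
    return 1.0 - float(np.dot(a, cdf))


def conditioning_sf(q, lam, tol=1e-13):
    """Tail probability by recursive conditioning (r <= 3 only: the nested
    adaptive quadrature grows exponentially with r)."""
    lam = list(lam)
    if len(lam) == 1:
        return stats.chi2.sf(q / lam[0], 1)

    def tail(qq, rest):
        if qq <= 0:
            return 1.0
        if len(rest) == 1:
            return stats.chi2.sf(qq / rest[0], 1)
        inner, _ = integrate.quad(
            lambda y: tail(qq - rest[0] * y, rest[1:])
            * stats.chi2.pdf(y, 1),
            0, qq / rest[0], epsabs=tol, limit=300)
        return inner + stats.chi2.sf(qq / rest[0], 1)

    return tail(q, lam)
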