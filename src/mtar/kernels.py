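"""Random-effects covariance kernels for multi-trait rare-variant tests.

The tested model treats the stacked genetic effects beta (m variants x K
traits, trait-major) as zero-mean random effects with covariance sigma * B,
where B = B2 (x) B1 factorizes into an among-variant kernel B1 = W1 O1 W1
and an among-trait kernel B2 = W2 O2 W2. O1 is exchangeable with
correlation rho1 (rho1 = 0 recovers SKAT, rho1 = 1 a burden test in the
single-trait case). O2 interpolates between structures guided by the
genome-wide genetic-correlation matrix C:

* iMTAR: off-diagonal rho2 * C_kk' (completely heterogeneous at rho2 = 0)
* cMTAR: off-diagonal rho2 * C_kk' + (1 - rho2) (homogeneous at rho2 = 0)

W1 carries per-variant weights (default the Beta(1, 25) density of the MAF,
as in SKAT) and W2 carries 0/1 trait-selection indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_GRID",
    "KernelSpec",
    "variant_weights",
    "build_variant_kernel",
    "build_trait_kernel",
    "build_effect_kernel",
    "grid_points",
]

#: rho grid searched by the combined tests: {0, 0.5, 1} for rho1 and rho2.
DEFAULT_GRID = ((0.0, 0.5, 1.0), (0.0, 0.5, 1.0))

STRUCTURES = ("iMTAR", "cMTAR")


def grid_points(grid=DEFAULT_GRID) -> list[tuple[float, float]]:
    """All (rho1, rho2) combinations of the grid (9 by default)."""
    rho1s, rho2s = grid
    return [(float(r1), float(r2)) for r1 in rho1s for r2 in rho2s]


def variant_weights(maf, scheme: str = "beta_1_25") -> np.ndarray:
    """Per-variant weights from the MAF.

    ``beta_1_25``: Beta(1, 25) density, 25 * (1 - MAF)^24, upweighting the
    rarest variants. ``flat``: unit weights. An array-like is accepted as a
    user-supplied scheme.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0.0) | (maf >= 1.0)):
        raise ValueError("MAF must lie strictly in (0, 1); monomorphic "
                         "variants must be removed first")
    if isinstance(scheme, str):
        if scheme == "beta_1_25":
            return stats.beta.pdf(maf, 1.0, 25.0)
        if scheme == "flat":
            return np.ones_like(maf)
        raise ValueError(f"unknown weight scheme {scheme!r}")
    w = np.asarray(scheme, dtype=float)
    if w.shape != maf.shape:
        raise ValueError("user-supplied weights must match number of variants")
    return w


def _exchangeable(dim: int, rho: float) -> np.ndarray:
    omega = np.full((dim, dim), rho)
    np.fill_diagonal(omega, 1.0)
    return omega


def build_variant_kernel(rho1: float, weights) -> np.ndarray:
    """B1 = W1 O1 W1 with exchangeable O1 (unit diagonal, off-diag rho1)."""
    if not 0.0 <= rho1 <= 1.0:
        raise ValueError("rho1 must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    omega = _exchangeable(w.size, rho1)
    return omega * np.outer(w, w)


def build_trait_kernel(rho2: float, C, structure: str,
                       indicators=None) -> np.ndarray:
    """B2 = W2 O2 W2 for one of the two among-trait structures."""
    if not 0.0 <= rho2 <= 1.0:
        raise ValueError("rho2 must lie in [0, 1]")
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}")
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("C must have unit diagonal")
    if np.linalg.eigvalsh(C).min() < -1e-8:
        raise ValueError("C is not positive semi-definite; repair it before "
                         "building kernels")
    K = C.shape[0]
    if structure == "iMTAR":
        omega = rho2 * C + (1.0 - rho2) * np.eye(K)
    else:
        omega = rho2 * C + (1.0 - rho2) * np.ones((K, K))
    np.fill_diagonal(omega, 1.0)
    if indicators is None:
        d = np.ones(K)
    else:
        d = np.asarray(indicators, dtype=float)
        if d.size != K or not np.all(np.isin(d, (0.0, 1.0))):
            raise ValueError("trait indicators must be a 0/1 vector of "
                             "length K")
    return omega * np.outer(d, d)


@dataclass
class KernelSpec:
    """Assembled B = B2 (x) B1 with its parameters (trait-major ordering)."""

    rho1: float
    rho2: float
    structure: str
    weights: np.ndarray
    C: np.ndarray
    indicators: np.ndarray
    B1: np.ndarray = field(repr=False, default=None)
    B2: np.ndarray = field(repr=False, default=None)
    B: np.ndarray = field(repr=False, default=None)

    @property
    def n_variants(self) -> int:
        return self.B1.shape[0]

    @property
    def n_traits(self) -> int:
        return self.B2.shape[0]


def build_effect_kernel(rho1: float, rho2: float, structure: str, maf=None,
                        C=None, weights=None, weight_scheme: str = "beta_1_25",
                        indicators=None) -> KernelSpec:
    """Assemble the full mK x mK effect covariance B = B2 (x) B1.

    Either ``maf`` (from which weights are derived via ``weight_scheme``) or
    explicit ``weights`` must be given. ``C`` defaults to the identity
    (no genetic-correlation guidance).
    """
    if weights is None:
        if maf is None:
            raise ValueError("supply either maf or explicit weights")
        weights = variant_weights(maf, weight_scheme)
    w = np.asarray(weights, dtype=float)
    if C is None:
        C = np.eye(1)
    C = np.asarray(C, dtype=float)
    B1 = build_variant_kernel(rho1, w)
    B2 = build_trait_kernel(rho2, C, structure, indicators)
    ind = (np.ones(C.shape[0]) if indicators is None
           else np.asarray(indicators, float))
    B = np.kron(B2, B1)
    return KernelSpec(rho1=rho1, rho2=rho2, structure=structure, weights=w,
                      C=C, indicators=ind, B1=B1, B2=B2, B=B)
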