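"""Stable normal-distribution kernels shared across the estimator modules.

Everything here broadcasts over numpy arrays so that the simulator can
evaluate estimators for 10^5 trial replicates without Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import norm

_SQRT_2OPI = np.sqrt(2.0 / np.pi)
_SQRT2 = np.sqrt(2.0)

# Gauss-Legendre rule reused by the bivariate CDF; 96 nodes on an interval
# of length <= ~18 gives <= ~5e-15 for these smooth integrands.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)

# Lower integration cutoff on the standard normal scale: Phi(-9) ~ 1e-19.
_TAIL = 9.0


def mills_lower(d):
    """phi(d)/Phi(d), computed via erfcx so it is stable for d << 0."""
    d = np.asarray(d, dtype=float)
    return _SQRT_2OPI / special.erfcx(-d / _SQRT2)


def mills_upper(d):
    """phi(d)/(1 - Phi(d)), stable for d >> 0 (hazard of the normal)."""
    d = np.asarray(d, dtype=float)
    return _SQRT_2OPI / special.erfcx(d / _SQRT2)


def bvn_cdf(a, b, rho):
    """P(X <= a, Y <= b) for standard bivariate normal with correlation rho.

    Uses the conditioning identity
        Phi2(a, b; rho) = int_{-inf}^{a} phi(v) Phi((b - rho v)/sqrt(1-rho^2)) dv
    evaluated with a fixed Gauss-Legendre rule, broadcasting over a and b.
    |rho| must be < 1 (the sequential designs here always have rho in (0,1)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    s = np.sqrt(1.0 - rho * rho)

    hi = np.clip(a, -_TAIL, _TAIL)
    lo = -_TAIL
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    # nodes: shape (..., n)
    v = mid[..., None] + half[..., None] * _GL_NODES
    integrand = norm.pdf(v) * norm.cdf((b[..., None] - rho * v) / s)
    out = half * np.einsum("...n,n->...", integrand, _GL_WEIGHTS)
    # a below the cutoff: probability is numerically zero
    out = np.where(a <= -_TAIL, 0.0, out)
    return out if out.ndim else float(out)


def vector_bisect(f, lo, hi, iters=60):
    """Vectorized bisection for a root of f between lo and hi (elementwise).

    f must be monotone on each bracket and broadcast over arrays; the caller
    guarantees a sign change. 60 halvings of an O(1) bracket reach machine
    precision.
    """
    lo = np.asarray(lo, dtype=float).copy()
    hi = np.asarray(hi, dtype=float).copy()
    flo = np.sign(f(lo))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = np.sign(f(mid))
        take_lo = fm == flo
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    out = 0.5 * (lo + hi)
    return out if out.ndim else float(out)
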