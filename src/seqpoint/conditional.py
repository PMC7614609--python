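"""Conditional-perspective estimators, given continuation to stage 2.

Conditioning on the event {T = 2} (the interim statistic stayed below the
efficacy boundary) reverses the direction of the MLE's bias: among continuing
trials the overall MLE is pulled *down*, so every conditional correction here
moves the estimate up. The module provides

* the analytic conditional bias of the overall MLE at the final analysis,
* the conditional bias-corrected MLE (CBC-MLE),
* the UMVCUE: Rao-Blackwellization of the (conditionally unbiased) stage-2
  MLE,
* the conditional density/CDF of the overall MLE given continuation, and
* the conditional median-unbiased estimator (CMUE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._normal import bvn_cdf, mills_lower, vector_bisect
from .design import TrialInformation
from .unconditional import _umvue_vec

__all__ = [
    "ConditionalEstimates",
    "conditional_bias_final",
    "cbc_mle",
    "umvcue",
    "conditional_mle_density",
    "conditional_mle_cdf",
    "cmue",
    "compute_conditional",
]


@dataclass(frozen=True)
class ConditionalEstimates:
    mle_stage2: float
    cbc_mle: float
    umvcue: float
    cmue: float


def conditional_bias_final(theta, info: TrialInformation):
    """Conditional bias of the overall MLE given continuation to stage 2.

    bias(theta | T=2) = -(sqrt(I1)/I2) * phi(d)/Phi(d), d = e - theta sqrt(I1).
    Strictly negative: continuation censors large interim effects. The Mills
    ratio is evaluated through erfcx, so the expression stays finite and
    accurate however deep d goes into the lower tail.
    """
    theta = np.asarray(theta, dtype=float)
    d = info.e - theta * np.sqrt(info.i1)
    out = -(np.sqrt(info.i1) / info.i2) * mills_lower(d)
    return out if out.ndim else float(out)


def _cbc_mle_vec(theta_obs, info: TrialInformation):
    """Vectorized CBC-MLE: root of theta_obs - bias(theta | T=2) - theta = 0.

    g is strictly decreasing (the Mills ratio has derivative in (-1, 0), so
    |d bias/d theta| <= I1/I2 < 1) and g(theta_obs) > 0, g -> -inf upward:
    the root is unique and above theta_obs.
    """
    theta_obs = np.asarray(theta_obs, dtype=float)

    def g(th):
        return theta_obs - conditional_bias_final(th, info) - th

    lo = theta_obs
    width = 10.0 / np.sqrt(info.i2)
    for _ in range(6):
        hi = theta_obs + width
        if np.all(g(hi) < 0):
            return vector_bisect(g, lo, hi)
        width *= 2.0
    raise RuntimeError("failed to bracket the CBC-MLE root")


def cbc_mle(info: TrialInformation) -> float:
    """Conditional bias-corrected MLE (upward fixed-point correction)."""
    return float(_cbc_mle_vec(info.theta_obs, info))


def _umvcue_vec(theta_obs, info: TrialInformation):
    """Vectorized UMVCUE via the information-weighted decomposition.

    theta_obs = (I1 theta1 + (I2-I1) theta2)/I2 on the canonical scale, so
    E[theta2 | T=2, theta_obs] = (I2 theta_obs - I1 m) / (I2 - I1) with m the
    truncated-normal mean that defines the UMVUE.
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    m = _umvue_vec(theta_obs, info)
    out = (info.i2 * theta_obs - info.i1 * m) / (info.i2 - info.i1)
    return out if np.ndim(out) else float(out)


def umvcue(info: TrialInformation) -> float:
    """Uniformly minimum variance conditionally unbiased estimator.

    Rao-Blackwellization of the stage-2 MLE given (T=2, theta_obs); satisfies
    I1 * UMVUE + (I2 - I1) * UMVCUE = I2 * theta_obs exactly.
    """
    if info.i2 <= info.i1:
        raise ValueError("UMVCUE requires I2 > I1 (some stage-2 information)")
    return float(_umvcue_vec(info.theta_obs, info))


def conditional_mle_density(m, theta, info: TrialInformation):
    """Density of the overall MLE at m, given continuation, under effect theta.

    f(m | T=2; theta) = sqrt(I2) phi(z2 - theta sqrt(I2))
        * Phi((e - theta sqrt(I1) - rho (z2 - theta sqrt(I2))) / sqrt(1-rho^2))
        / Phi(e - theta sqrt(I1)),       z2 = m sqrt(I2), rho = sqrt(I1/I2).
    """
    m = np.asarray(m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    rho = info.rho
    s = np.sqrt(1.0 - rho * rho)
    v = (m - theta) * np.sqrt(info.i2)  # standardized z2 residual
    d = info.e - theta * np.sqrt(info.i1)
    out = (
        np.sqrt(info.i2)
        * norm.pdf(v)
        * norm.cdf((d - rho * v) / s)
        / norm.cdf(d)
    )
    return out if np.ndim(out) else float(out)


def conditional_mle_cdf(m, theta, info: TrialInformation):
    """CDF of the overall MLE given continuation: Phi2(., .; rho)/Phi(.).

    Integrating the conditional density up to m gives the closed reduction
    F(m | T=2; theta) = Phi2((m - theta) sqrt(I2), e - theta sqrt(I1); rho)
                        / Phi(e - theta sqrt(I1)).
    """
    m = np.asarray(m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    a = (m - theta) * np.sqrt(info.i2)
    d = info.e - theta * np.sqrt(info.i1)
    out = bvn_cdf(a, d, info.rho) / norm.cdf(d)
    return out if np.ndim(out) else float(out)


def _cmue_vec(theta_obs, info: TrialInformation):
    """Vectorized CMUE: theta whose conditional median equals theta_obs.

    F(theta_obs | T=2; theta) is strictly decreasing in theta (stochastic
    ordering of the conditional law), so the root of F = 0.5 is unique.
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    width = 10.0 / np.sqrt(info.i2)

    def g(th):
        return conditional_mle_cdf(theta_obs, th, info) - 0.5

    for _ in range(3):
        lo, hi = theta_obs - width, theta_obs + width
        if np.all(g(lo) > 0) and np.all(g(hi) < 0):
            return vector_bisect(g, lo, hi)
        width *= 5.0
    raise RuntimeError("failed to bracket the CMUE root")


def cmue(info: TrialInformation) -> float:
    """Conditional median-unbiased estimator."""
    return float(_cmue_vec(info.theta_obs, info))


def compute_conditional(
    info: TrialInformation, mle_stage2: float | None = None
) -> ConditionalEstimates:
    """All conditional estimators for a trial that continued to stage 2.

    mle_stage2, if given, is the stage-2 MLE from the incremental (post-
    interim) counts; otherwise the canonical information-weighted
    decomposition (I2 theta_obs - I1 theta1)/(I2 - I1) is used. On real
    binary data the two differ slightly because the pooled variance is
    re-estimated at each analysis; on the canonical scale they coincide.
    """
    if mle_stage2 is None:
        mle_stage2 = (info.i2 * info.theta_obs - info.i1 * info.theta1) / (
            info.i2 - info.i1
        )
    return ConditionalEstimates(
        mle_stage2=float(mle_stage2),
        cbc_mle=cbc_mle(info),
        umvcue=umvcue(info),
        cmue=cmue(info),
    )
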