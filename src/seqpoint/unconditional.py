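"""Unconditional-perspective estimators for a two-stage efficacy design.

Given the sufficient quantities (I1, I2, z2, theta_obs, e) of a trial that
continued to the second stage, this module provides

* the analytic unconditional (marginal) bias of the overall MLE,
* the unconditional bias-corrected MLE (UBC-MLE): the fixed point of
  theta = theta_obs - bias(theta),
* the UMVUE: the Rao-Blackwellization of the (unconditionally unbiased)
  stage-1 MLE on the sufficient statistic,
* the stagewise-ordering P-value function P(theta), and
* the median-unbiased estimator (MUE): the root of P(theta) = 0.5.

All functions accept numpy arrays for the observed statistics and broadcast,
which is what lets the simulator evaluate them per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._normal import bvn_cdf, mills_lower, vector_bisect
from .design import TrialInformation

__all__ = [
    "UnconditionalEstimates",
    "emerson_bias",
    "ubc_mle",
    "umvue",
    "stagewise_pvalue",
    "mue",
    "compute_unconditional",
]

_PHI_MAX = 1.0 / np.sqrt(2.0 * np.pi)  # max of the standard normal density


@dataclass(frozen=True)
class UnconditionalEstimates:
    mle_overall: float
    mle_stage1: float
    ubc_mle: float
    umvue: float
    mue: float


def emerson_bias(theta, info: TrialInformation):
    """Unconditional bias of the overall MLE at true effect theta.

    bias(theta) = ((I2 - I1) / (I2 sqrt(I1))) * phi(e - theta sqrt(I1)).
    Strictly positive for finite boundaries: early stopping selects large
    interim effects, inflating the marginal mean of the MLE.
    """
    theta = np.asarray(theta, dtype=float)
    c = (info.i2 - info.i1) / (info.i2 * np.sqrt(info.i1))
    out = c * norm.pdf(info.e - theta * np.sqrt(info.i1))
    return out if out.ndim else float(out)


def _ubc_mle_vec(theta_obs, info: TrialInformation):
    """Vectorized UBC-MLE: root of theta_obs - bias(theta) - theta = 0.

    g(theta) is strictly decreasing (|d bias/d theta| < 1 for I1 < I2), and
    bias is bounded by c * phi(0), so the bracket below always holds a root.
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    c = (info.i2 - info.i1) / (info.i2 * np.sqrt(info.i1))

    def g(th):
        return theta_obs - emerson_bias(th, info) - th

    lo = theta_obs - c * _PHI_MAX - 1e-12
    hi = theta_obs
    return vector_bisect(g, lo, hi)


def ubc_mle(info: TrialInformation) -> float:
    """Unconditional bias-corrected MLE (Whitehead's fixed-point correction)."""
    return float(_ubc_mle_vec(info.theta_obs, info))


def _umvue_vec(theta_obs, info: TrialInformation):
    """Rao-Blackwell form of the UMVUE for replicates that continued.

    Conditional on the overall MLE and on continuation, the stage-1 MLE is
    normal with mean theta_obs and SD sqrt(1/I1 - 1/I2), truncated above at
    the effect-scale boundary e/sqrt(I1); the UMVUE is that truncated mean.
    """
    theta_obs = np.asarray(theta_obs, dtype=float)
    sigma_c = np.sqrt(1.0 / info.i1 - 1.0 / info.i2)
    a = (info.effect_scale_boundary - theta_obs) / sigma_c
    out = theta_obs - sigma_c * mills_lower(a)
    return out if out.ndim else float(out)


def umvue(info: TrialInformation, stopped_stage: int = 2) -> float:
    """Uniformly minimum variance unbiased estimator.

    At stage-1 stopping the stage-1 MLE is itself the UMVUE; after
    continuation it is the truncated-normal conditional mean of the stage-1
    MLE given the overall MLE.
    """
    if stopped_stage == 1:
        return info.theta1
    if stopped_stage != 2:
        raise ValueError("stopped_stage must be 1 or 2")
    return float(_umvue_vec(info.theta_obs, info))


def stagewise_pvalue(theta, info: TrialInformation, z2=None):
    """Stagewise-ordering P-value function P(theta) for a continuing trial.

    P(theta) = Pr_theta(Z1 >= e) + Pr_theta(Z1 < e, Z2 >= z2_obs): stage-1
    rejections are ordered as more extreme than any stage-2 outcome.  With
    the canonical bivariate normal law this collapses to

        P(theta) = 1 - Phi2(e - theta sqrt(I1), z2 - theta sqrt(I2); rho),

    rho = sqrt(I1/I2).  Strictly increasing in theta, limits 0 and 1.
    """
    theta = np.asarray(theta, dtype=float)
    z2 = info.z2 if z2 is None else np.asarray(z2, dtype=float)
    a = info.e - theta * np.sqrt(info.i1)
    b = z2 - theta * np.sqrt(info.i2)
    out = 1.0 - bvn_cdf(a, b, info.rho)
    return out if np.ndim(out) else float(out)


def _mue_vec(z2, info: TrialInformation):
    """Vectorized MUE: root of P(theta) = 0.5 for each observed z2."""
    z2 = np.asarray(z2, dtype=float)
    center = z2 / np.sqrt(info.i2)
    width = 10.0 / np.sqrt(info.i2)

    def g(th):
        return stagewise_pvalue(th, info, z2=z2) - 0.5

    for _ in range(3):  # widen geometrically if the bracket misses
        lo, hi = center - width, center + width
        if np.all(g(lo) < 0) and np.all(g(hi) > 0):
            return vector_bisect(g, lo, hi)
        width *= 5.0
    raise RuntimeError("failed to bracket the MUE root")


def mue(info: TrialInformation) -> float:
    """Median-unbiased estimator under stagewise ordering."""
    return float(_mue_vec(info.z2, info))


def compute_unconditional(info: TrialInformation) -> UnconditionalEstimates:
    """All unconditional estimators for a trial that continued to stage 2."""
    return UnconditionalEstimates(
        mle_overall=info.theta_obs,
        mle_stage1=info.theta1,
        ubc_mle=ubc_mle(info),
        umvue=umvue(info, stopped_stage=2),
        mue=mue(info),
    )
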