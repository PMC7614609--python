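"""Canonical-joint-distribution simulator and estimator sampling distributions.

Trial replicates are drawn on the z scale from the asymptotic canonical joint
distribution of the sequential standardized statistics: (Z1, Z2) bivariate
normal with means (theta sqrt(I1), theta sqrt(I2)), unit variances and
correlation sqrt(I1/I2). The efficacy rule Z1 >= e decides stopping. All
estimators are then evaluated per replicate (vectorized), giving their
sampling distributions, means/SDs overall and split by stopping stage, and
parametric-bootstrap standard errors.

Replicates that stop at stage 1 have every unconditional estimator equal to
the stage-1 MLE: by definition for the overall MLE, MUE and UMVUE, and by
convention for the UBC-MLE (whose correction would need the unobserved I2).
Conditional estimators are evaluated over continuing replicates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .conditional import _cbc_mle_vec, _cmue_vec, _umvcue_vec
from .design import TrialInformation
from .unconditional import _mue_vec, _ubc_mle_vec, _umvue_vec

__all__ = [
    "TrialReplicates",
    "SimResult",
    "UNCONDITIONAL_ESTIMATORS",
    "CONDITIONAL_ESTIMATORS",
    "simulate_replicates",
    "sampling_distribution",
    "evaluate_estimators",
    "bootstrap_se",
]

UNCONDITIONAL_ESTIMATORS = ("mle_overall", "mle_stage1", "mue", "umvue", "ubc_mle")
CONDITIONAL_ESTIMATORS = ("mle_stage2", "cmue", "umvcue", "cbc_mle")


@dataclass(frozen=True)
class TrialReplicates:
    """Vectors of simulated trial outcomes at one (theta, design) setting."""

    theta: float
    z1: np.ndarray
    z2: np.ndarray  # latent second-stage statistic, kept for all replicates
    stopped_stage: np.ndarray  # 1 where z1 >= e, else 2

    @property
    def n_reps(self) -> int:
        return self.z1.size

    @property
    def continuing(self) -> np.ndarray:
        return self.stopped_stage == 2

    @property
    def stop_fraction(self) -> float:
        return float(np.mean(self.stopped_stage == 1))


@dataclass(frozen=True)
class SimResult:
    """Estimator summaries at one true effect.

    overall: per-estimator mean/SD, unconditional rows over all replicates and
    conditional rows over continuing replicates.
    by_stage: unconditional estimators split by stopping stage.
    """

    theta: float
    n_reps: int
    stop_fraction: float
    overall: pd.DataFrame
    by_stage: pd.DataFrame


def simulate_replicates(
    theta: float, info: TrialInformation, n_reps: int, seed
) -> TrialReplicates:
    """Draw n_reps trials from the canonical joint distribution at theta.

    seed may be an int or a numpy Generator; a fixed seed reproduces the
    replicate set exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(seed)
    rho = info.rho
    z1 = rng.standard_normal(n_reps) + theta * np.sqrt(info.i1)
    eps = rng.standard_normal(n_reps)
    z2 = (
        theta * np.sqrt(info.i2)
        + rho * (z1 - theta * np.sqrt(info.i1))
        + np.sqrt(1.0 - rho * rho) * eps
    )
    stopped = np.where(z1 >= info.e, 1, 2).astype(np.int8)
    return TrialReplicates(theta=float(theta), z1=z1, z2=z2, stopped_stage=stopped)


def sampling_distribution(
    replicates: TrialReplicates, info: TrialInformation
) -> dict[str, np.ndarray]:
    """Per-replicate estimates for every estimator.

    Unconditional vectors have length n_reps (stage-1 stoppers contribute the
    stage-1 MLE); conditional vectors cover continuing replicates only. The
    stage-2 MLE uses the information-weighted decomposition
    (I2 theta_obs - I1 theta1)/(I2 - I1), exact on the canonical scale.
    """
    cont = replicates.continuing
    theta1 = replicates.z1 / np.sqrt(info.i1)
    theta_obs_c = replicates.z2[cont] / np.sqrt(info.i2)
    theta1_c = theta1[cont]
    z2_c = replicates.z2[cont]

    out: dict[str, np.ndarray] = {}
    for name in UNCONDITIONAL_ESTIMATORS:
        out[name] = theta1.copy()
    if np.any(cont):
        out["mle_overall"][cont] = theta_obs_c
        out["umvue"][cont] = _umvue_vec(theta_obs_c, info)
        out["ubc_mle"][cont] = _ubc_mle_vec(theta_obs_c, info)
        out["mue"][cont] = _mue_vec(z2_c, info)
        out["mle_stage2"] = (info.i2 * theta_obs_c - info.i1 * theta1_c) / (
            info.i2 - info.i1
        )
        out["umvcue"] = _umvcue_vec(theta_obs_c, info)
        out["cbc_mle"] = _cbc_mle_vec(theta_obs_c, info)
        out["cmue"] = _cmue_vec(theta_obs_c, info)
    else:
        warn("no replicates continued to stage 2; conditional block is empty")
        for name in CONDITIONAL_ESTIMATORS:
            out[name] = np.empty(0)
    return out


def evaluate_estimators(
    replicates: TrialReplicates, info: TrialInformation
) -> SimResult:
    """Summarize all estimators over the replicate set."""
    samples = sampling_distribution(replicates, info)
    cont = replicates.continuing

    rows = []
    for name in UNCONDITIONAL_ESTIMATORS:
        v = samples[name]
        rows.append(("unconditional", name, v.mean(), v.std(ddof=1)))
    for name in CONDITIONAL_ESTIMATORS:
        v = samples[name]
        if v.size:
            rows.append(("conditional", name, v.mean(), v.std(ddof=1)))
        else:
            rows.append(("conditional", name, np.nan, np.nan))
    overall = pd.DataFrame(
        rows, columns=["perspective", "estimator", "mean", "sd"]
    )

    stage_rows = []
    stopped = ~cont
    if np.any(stopped):
        v = samples["mle_stage1"][stopped]
        stage_rows.append(("stage1", "mle_stage1", v.mean(), v.std(ddof=1)))
    for name in UNCONDITIONAL_ESTIMATORS:
        v = samples[name][cont]
        if v.size:
            stage_rows.append(("stage2", name, v.mean(), v.std(ddof=1)))
    by_stage = pd.DataFrame(
        stage_rows, columns=["stage", "estimator", "mean", "sd"]
    )

    return SimResult(
        theta=replicates.theta,
        n_reps=replicates.n_reps,
        stop_fraction=replicates.stop_fraction,
        overall=overall,
        by_stage=by_stage,
    )


def bootstrap_se(
    theta_assumed: float, info: TrialInformation, n_reps: int, seed
) -> pd.DataFrame:
    """Parametric-bootstrap SEs for all estimators at an assumed true effect.

    Replicates are drawn from the canonical joint distribution at
    theta_assumed; each estimator's SE is its SD across replicates
    (unconditional estimators over all replicates, conditional estimators
    over continuing replicates only).
    """
    if n_reps < 1000:
        raise ValueError("bootstrap needs at least 10^3 replicates")
    reps = simulate_replicates(theta_assumed, info, n_reps, seed)
    result = evaluate_estimators(reps, info)
    table = result.overall[["perspective", "estimator", "sd"]].rename(
        columns={"sd": "se"}
    )
    return table.reset_index(drop=True)
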