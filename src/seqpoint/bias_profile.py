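"""Analytic bias and stopping-probability curves over the true effect.

For a two-stage design with interim efficacy boundary e (z scale) and
observed informations I1 < I2, the four curves are

* bias_given_stop(theta): E[theta1 | Z1 >= e] - theta > 0,
* bias_given_continue(theta): E[theta_obs | T=2] - theta < 0,
* unconditional_bias(theta): the marginal bias of the overall MLE > 0,
* stopping_probability(theta): Pr(Z1 >= e) = 1 - Phi(e - theta sqrt(I1)).

They satisfy the law of total expectation exactly:
p * bias_given_stop + (1 - p) * bias_given_continue = unconditional_bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._normal import mills_upper
from .conditional import conditional_bias_final
from .design import TrialInformation, obf_design
from .unconditional import emerson_bias

__all__ = [
    "BiasProfile",
    "stopping_probability",
    "bias_given_stop",
    "bias_given_continue",
    "unconditional_bias",
    "profile",
    "normal_endpoint_information",
    "two_stage_normal_scenario",
]


@dataclass(frozen=True)
class BiasProfile:
    theta_grid: np.ndarray
    bias_given_stop: np.ndarray
    bias_given_continue: np.ndarray
    unconditional_bias: np.ndarray
    stop_probability: np.ndarray

    def to_frame(self):
        """Five-column table (theta plus the four curves) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "theta": self.theta_grid,
                "bias_given_stop": self.bias_given_stop,
                "bias_given_continue": self.bias_given_continue,
                "unconditional_bias": self.unconditional_bias,
                "stop_probability": self.stop_probability,
            }
        )


def stopping_probability(theta, info: TrialInformation):
    """Probability of crossing the interim efficacy boundary under theta."""
    theta = np.asarray(theta, dtype=float)
    out = norm.sf(info.e - theta * np.sqrt(info.i1))
    return out if np.ndim(out) else float(out)


def bias_given_stop(theta, info: TrialInformation):
    """Conditional over-estimation among trials that stop early.

    E[theta1 | Z1 >= e] - theta = phi(d) / ((1 - Phi(d)) sqrt(I1)),
    d = e - theta sqrt(I1); the upper Mills ratio is erfcx-guarded so the
    expression is stable far beyond d = 8.
    """
    theta = np.asarray(theta, dtype=float)
    d = info.e - theta * np.sqrt(info.i1)
    out = mills_upper(d) / np.sqrt(info.i1)
    return out if np.ndim(out) else float(out)


def bias_given_continue(theta, info: TrialInformation):
    """Conditional under-estimation at the final analysis (negative)."""
    return conditional_bias_final(theta, info)


def unconditional_bias(theta, info: TrialInformation):
    """Marginal bias of the overall MLE (positive)."""
    return emerson_bias(theta, info)


def profile(info: TrialInformation, theta_grid) -> BiasProfile:
    """Evaluate all four curves on a grid of true effects."""
    grid = np.asarray(theta_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("theta_grid must be finite")
    return BiasProfile(
        theta_grid=grid,
        bias_given_stop=np.asarray(bias_given_stop(grid, info)),
        bias_given_continue=np.asarray(bias_given_continue(grid, info)),
        unconditional_bias=np.asarray(unconditional_bias(grid, info)),
        stop_probability=np.asarray(stopping_probability(grid, info)),
    )


def normal_endpoint_information(n_per_arm: float, sd: float = 1.0) -> float:
    """Information for a two-arm normal endpoint with equal allocation.

    Var(difference in means) = 2 sd^2 / n per-arm, so I = n / (2 sd^2).
    """
    if n_per_arm <= 0 or sd <= 0:
        raise ValueError("n_per_arm and sd must be positive")
    return n_per_arm / (2.0 * sd * sd)


def two_stage_normal_scenario(
    n_total: int, sd: float = 1.0, alpha: float = 0.05
) -> TrialInformation:
    """Two-stage OBF scenario for a normal endpoint, interim at 50% information.

    Used for the small/medium/large illustrative designs (total N of 40, 100
    and 620, detecting effects of roughly 0.8, 0.5 and 0.2 with 80% power at
    one-sided alpha = 0.05). Observed-statistic fields are placeholders
    (z scale 0): the profile curves depend only on (I1, I2, e).
    """
    design = obf_design(2, alpha, (0.5, 1.0))
    i2 = normal_endpoint_information(n_total / 2.0, sd)
    i1 = 0.5 * i2
    return TrialInformation(
        i1=i1, i2=i2, z1=0.0, z2=0.0, theta1=0.0, theta_obs=0.0,
        e=design.z_boundaries[0],
    )
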