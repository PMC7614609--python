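"""Count-file parsing, design configuration, and estimate reporting.

File conventions:

* counts file — CSV with one row per analysis, columns
  analysis_index, successes_control, total_control, successes_treatment,
  total_treatment (cumulative counts at each analysis);
* design config — YAML or JSON with keys stages, alpha and optionally
  info_fractions; unknown keys are rejected.

The bundled example dataset is the MUSEC trial (oral cannabis extract versus
placebo for muscle stiffness in multiple sclerosis): a two-stage design with
one-sided O'Brien-Fleming efficacy boundaries (2.797, 1.977) that continued
to its final analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .conditional import compute_conditional
from .design import (
    AnalysisCounts,
    TrialInformation,
    incremental_counts,
    mle_difference,
    trial_information,
)
from .unconditional import compute_unconditional

__all__ = [
    "COUNTS_COLUMNS",
    "EstimateReport",
    "read_counts_csv",
    "read_design_config",
    "load_musec_counts",
    "MUSEC_BOUNDARIES",
    "musec_information",
    "estimate_report",
    "report_to_frame",
    "write_report",
]

COUNTS_COLUMNS = (
    "analysis_index",
    "successes_control",
    "total_control",
    "successes_treatment",
    "total_treatment",
)

#: z-scale O'Brien-Fleming boundaries of the MUSEC design as displayed in the
#: trial report (interim, final), rounded to 3 dp. The estimators condition on
#: the interim boundary; musec_information() re-solves it at full precision
#: (2.796451..., matching 2.797 after rounding) because estimates sensitive at
#: the 4th decimal (the MUE) need the unrounded design value.
MUSEC_BOUNDARIES = (2.797, 1.977)

_DESIGN_KEYS = {"stages", "alpha", "info_fractions"}


@dataclass(frozen=True)
class EstimateReport:
    """One estimator's entry in a trial report."""

    estimator: str
    perspective: str  # unconditional | conditional | naive
    estimate: float
    mle_overall: float
    se: float | None = None

    @property
    def relative_difference_to_mle(self) -> int:
        """Signed percent difference to the overall MLE, whole percents."""
        return round(
            100.0 * (self.estimate - self.mle_overall) / self.mle_overall
        )


def read_counts_csv(path) -> list[AnalysisCounts]:
    """Parse a cumulative-counts CSV into per-analysis AnalysisCounts."""
    df = pd.read_csv(path)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts file {path}: missing columns {sorted(missing)}")
    df = df.sort_values("analysis_index")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                AnalysisCounts(
                    successes_control=int(row.successes_control),
                    total_control=int(row.total_control),
                    successes_treatment=int(row.successes_treatment),
                    total_treatment=int(row.total_treatment),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"counts file {path}, data row {i + 1}: {err}") from err
    if not out:
        raise ValueError(f"counts file {path} holds no analyses")
    return out


def read_design_config(path) -> dict:
    """Parse a strict design config (YAML or JSON)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(cfg, dict):
        raise ValueError(f"design config {path} must be a mapping")
    unknown = set(cfg) - _DESIGN_KEYS
    if unknown:
        raise ValueError(f"design config {path}: unknown keys {sorted(unknown)}")
    for key in ("stages", "alpha"):
        if key not in cfg:
            raise ValueError(f"design config {path}: missing key '{key}'")
    return cfg


def load_musec_counts() -> tuple[AnalysisCounts, AnalysisCounts]:
    """Interim and final cumulative counts of the bundled MUSEC dataset."""
    ref = resources.files("seqpoint.data") / "musec_counts.csv"
    with resources.as_file(ref) as path:
        counts = read_counts_csv(path)
    return counts[0], counts[1]


def musec_design():
    """The MUSEC group sequential design: two-stage one-sided OBF, alpha 0.025.

    Solving C(2, 0.025) gives boundaries (2.7965, 1.9774), the full-precision
    values behind the displayed (2.797, 1.977).
    """
    from .design import obf_design

    return obf_design(2, 0.025, (0.5, 1.0))


def musec_information(boundary: float | None = None) -> TrialInformation:
    """TrialInformation of the MUSEC trial, pooled-variance convention.

    boundary defaults to the full-precision interim OBF boundary from
    musec_design(); pass MUSEC_BOUNDARIES[0] to condition on the rounded
    display value instead (the estimates differ only in the 4th decimal).
    """
    if boundary is None:
        boundary = musec_design().z_boundaries[0]
    interim, final = load_musec_counts()
    return trial_information(interim, final, e=boundary)


def estimate_report(
    interim: AnalysisCounts,
    final: AnalysisCounts,
    e: float,
    se_table: pd.DataFrame | None = None,
) -> list[EstimateReport]:
    """Full estimator suite for a trial that continued to the final analysis.

    The stage-2 MLE is computed from the incremental (post-interim) counts.
    se_table, if given, is a bootstrap_se frame whose 'se' column is attached
    by estimator name.
    """
    info = trial_information(interim, final, e)
    if info.z1 >= e:
        raise ValueError(
            "interim statistic crossed the efficacy boundary; the trial "
            "would have stopped at stage 1 and the conditional estimators "
            "are undefined"
        )
    unc = compute_unconditional(info)
    stage2_mle = mle_difference(incremental_counts(interim, final))
    cond = compute_conditional(info, mle_stage2=stage2_mle)

    ses = {}
    if se_table is not None:
        ses = dict(zip(se_table["estimator"], se_table["se"]))

    entries = [
        ("mle_overall", "naive", unc.mle_overall),
        ("mle_stage1", "unconditional", unc.mle_stage1),
        ("mue", "unconditional", unc.mue),
        ("umvue", "unconditional", unc.umvue),
        ("ubc_mle", "unconditional", unc.ubc_mle),
        ("mle_stage2", "conditional", cond.mle_stage2),
        ("cmue", "conditional", cond.cmue),
        ("umvcue", "conditional", cond.umvcue),
        ("cbc_mle", "conditional", cond.cbc_mle),
    ]
    return [
        EstimateReport(
            estimator=name,
            perspective=persp,
            estimate=value,
            mle_overall=unc.mle_overall,
            se=ses.get(name),
        )
        for name, persp, value in entries
    ]


def report_to_frame(report: list[EstimateReport]) -> pd.DataFrame:
    """Tabulate a report: estimate to 4 dp, SE to 3 dp, whole-percent diffs."""
    return pd.DataFrame(
        {
            "estimator": [r.estimator for r in report],
            "perspective": [r.perspective for r in report],
            "estimate": [round(r.estimate, 4) for r in report],
            "se": [None if r.se is None else round(r.se, 3) for r in report],
            "relative_difference_pct": [
                0 if r.estimator == "mle_overall" else r.relative_difference_to_mle
                for r in report
            ],
        }
    )


def write_report(report: list[EstimateReport], path, fmt: str = "csv") -> None:
    """Write a report as CSV (rounded) or JSON (full precision retained)."""
    path = Path(path)
    if fmt == "csv":
        report_to_frame(report).to_csv(path, index=False)
    elif fmt == "json":
        payload = [
            {
                "estimator": r.estimator,
                "perspective": r.perspective,
                "estimate": r.estimate,
                "se": r.se,
                "relative_difference_pct": (
                    0 if r.estimator == "mle_overall" else r.relative_difference_to_mle
                ),
            }
            for r in report
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format: {fmt}")
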