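"""Seeded synthetic screening-cohort generator.

Produces per-subject records mirroring the statistical structure of a small
prospective pregnancy cohort: a fixed disease prevalence, a screening call at
each follow-up week drawn with per-week sensitivity/specificity, and paired
start/end-of-pregnancy immunoassay concentrations drawn log-normally with a
detection floor below which a reading is 'undetectable'.

Defaults mirror the study conditions the diagnostics module is meant to
evaluate: 28 subjects, 25% prevalence, follow-up weeks 11/24/36 with the
per-week call accuracies implied by the screening tables, and assay levels in
the 0.05–2 ng/mL range with no systematic difference between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import ElisaPair

__all__ = ["CohortSpec", "generate_cohort", "write_cohort_csv", "read_cohort_csv",
           "cohort_calls", "cohort_elisa_pairs"]

#: Per-week (sensitivity, specificity) of the screening call, defaults chosen
#: to mirror the three-timepoint screening pattern evaluated by diagnostics.
DEFAULT_TIMEPOINTS: dict[int, tuple[float, float]] = {
    11: (1 / 7, 1.0),
    24: (6 / 7, 1.0),
    36: (6 / 7, 19 / 21),
}

MISSING = "NA"
UNDETECTABLE = "undetectable"


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 28
    prevalence: float = 0.25
    timepoints: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINTS)
    )
    # log-normal parameters (mean, sd of log concentration) per outcome group
    elisa_log_mean_pe: float = -0.7
    elisa_log_sd_pe: float = 1.0
    elisa_log_mean_ctrl: float = -0.7
    elisa_log_sd_ctrl: float = 1.0
    undetectable_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for week, (sens, spec) in self.timepoints.items():
            if not (0 <= sens <= 1 and 0 <= spec <= 1):
                raise ValueError(f"rates for week {week} must be in [0, 1]")
        if self.undetectable_floor < 0:
            raise ValueError("undetectable_floor must be >= 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject × follow-up week, fully reproducible from the seed.

    Columns: subject_id, timepoint_week, pe_outcome (0/1), lcms_call (0/1),
    elisa_begin, elisa_end (floats; NaN where below the detection floor).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    outcome = rng.random(n) < spec.prevalence
    log_mean = np.where(outcome, spec.elisa_log_mean_pe, spec.elisa_log_mean_ctrl)
    log_sd = np.where(outcome, spec.elisa_log_sd_pe, spec.elisa_log_sd_ctrl)
    begin = np.exp(rng.normal(log_mean, log_sd))
    end = np.exp(rng.normal(log_mean, log_sd))
    begin[begin < spec.undetectable_floor] = np.nan
    end[end < spec.undetectable_floor] = np.nan

    rows = []
    for week in sorted(spec.timepoints):
        sens, specificity = spec.timepoints[week]
        p_call = np.where(outcome, sens, 1.0 - specificity)
        call = rng.random(n) < p_call
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"S{i + 1:03d}",
                    "timepoint_week": week,
                    "pe_outcome": int(outcome[i]),
                    "lcms_call": int(call[i]),
                    "elisa_begin": begin[i],
                    "elisa_end": end[i],
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["subject_id", "timepoint_week"], kind="stable").reset_index(drop=True)


def _format_conc(v: float) -> str:
    return UNDETECTABLE if pd.isna(v) else f"{v:.3f}"


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["elisa_begin"] = out["elisa_begin"].map(_format_conc)
    out["elisa_end"] = out["elisa_end"].map(_format_conc)
    out.to_csv(path, index=False, lineterminator="\n")


def _parse_conc(token: str) -> float:
    token = str(token).strip()
    if token in ("", MISSING, "-") or token.lower() == UNDETECTABLE:
        return float("nan")
    return float(token)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["elisa_begin"] = df["elisa_begin"].map(_parse_conc)
    df["elisa_end"] = df["elisa_end"].map(_parse_conc)
    return df


def cohort_calls(df: pd.DataFrame, week: int) -> tuple[list[bool], list[bool]]:
    """(calls, truth) for one follow-up week, ordered by subject id."""
    sub = df[df["timepoint_week"] == week].sort_values("subject_id")
    if sub.empty:
        raise ValueError(f"no records for week {week}")
    return [bool(v) for v in sub["lcms_call"]], [bool(v) for v in sub["pe_outcome"]]


def cohort_elisa_pairs(df: pd.DataFrame) -> list[ElisaPair]:
    sub = df.drop_duplicates("subject_id").sort_values("subject_id")
    return [
        ElisaPair(
            subject_id=row.subject_id,
            begin=None if pd.isna(row.elisa_begin) else float(row.elisa_begin),
            end=None if pd.isna(row.elisa_end) else float(row.elisa_end),
        )
        for row in sub.itertuples()
    ]
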