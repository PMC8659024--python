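"""Screening-test performance statistics with exact and delta-method CIs.

From a 2×2 confusion table (screening call vs. disease outcome) this module
computes sensitivity, specificity, likelihood ratios, prevalence, predictive
values and accuracy, each with the 95% confidence interval method standard
for that statistic:

* binomial proportions (sensitivity, specificity, prevalence, accuracy) —
  exact Clopper–Pearson intervals from beta quantiles;
* likelihood ratios — the Simel log method, CI = exp(ln LR ± z·SE) with
  SE(ln PLR) = √(1/TP − 1/n₁ + 1/FP − 1/n₀) and
  SE(ln NLR) = √(1/FN − 1/n₁ + 1/TN − 1/n₀);
* predictive values — the Mercaldo logit method, a delta-method variance on
  the logit scale back-transformed through the inverse logit.

z is taken as 1.96 exactly for the 95% level, the convention of the clinical
calculators these tables come from.  Statistics that a zero cell leaves
undefined (e.g. the positive likelihood ratio when FP = 0) are reported as
blank, never as infinity.

Also included: percent-change arithmetic for paired ELISA concentrations
with 'undetectable'/missing handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ConfusionTable",
    "DiagnosticStat",
    "ElisaPair",
    "point_estimates",
    "ci_proportion_cp",
    "ci_lr",
    "ci_pv",
    "percent_change",
    "diagnostic_report",
    "render_report",
]

Z_95 = 1.96  # exact, not norm.ppf(0.975)


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/TN/FN counts of screening calls against outcomes."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def n1(self) -> int:  # diseased
        return self.TP + self.FN

    @property
    def n0(self) -> int:  # non-diseased
        return self.TN + self.FP

    @classmethod
    def from_calls(cls, calls: Sequence[bool], truth: Sequence[bool]) -> "ConfusionTable":
        if len(calls) != len(truth):
            raise ValueError("calls and truth must be aligned and equal length")
        tp = sum(c and t for c, t in zip(calls, truth))
        fp = sum(c and not t for c, t in zip(calls, truth))
        tn = sum(not c and not t for c, t in zip(calls, truth))
        fn = sum(not c and t for c, t in zip(calls, truth))
        return cls(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass(frozen=True)
class DiagnosticStat:
    name: str
    estimate: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None
    percent: bool = False  # display scale: percentage vs plain ratio


@dataclass(frozen=True)
class ElisaPair:
    """Paired concentrations for one subject; None encodes undetectable/missing."""

    subject_id: str
    begin: float | None
    end: float | None

    def __post_init__(self) -> None:
        for v in (self.begin, self.end):
            if v is not None and v < 0:
                raise ValueError("concentrations must be >= 0")


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def point_estimates(t: ConfusionTable) -> dict[str, float | None]:
    """All point estimates; proportions on the 0–1 scale, None when undefined."""
    sens = _safe_div(t.TP, t.n1)
    spec = _safe_div(t.TN, t.n0)
    plr = None
    nlr = None
    if sens is not None and spec is not None:
        plr = _safe_div(sens, 1 - spec)  # undefined (blank) when FP = 0
        nlr = _safe_div(1 - sens, spec)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "PLR": plr,
        "NLR": nlr,
        "prevalence": t.n1 / t.n,
        "PPV": _safe_div(t.TP, t.TP + t.FP),
        "NPV": _safe_div(t.TN, t.TN + t.FN),
        "accuracy": (t.TP + t.TN) / t.n,
    }


def ci_proportion_cp(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper–Pearson interval for x successes in n trials (0–1 scale)."""
    if n < 1 or not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n and n >= 1")
    alpha = 1 - level
    low = 0.0 if x == 0 else float(_sps.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(_sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _z(level: float) -> float:
    return Z_95 if abs(level - 0.95) < 1e-12 else float(_sps.norm.ppf(1 - (1 - level) / 2))


def ci_lr(t: ConfusionTable, which: str, level: float = 0.95) -> tuple[float, float] | None:
    """Simel log-method CI for a likelihood ratio; None when a zero cell
    leaves the LR or its standard error undefined."""
    est = point_estimates(t)
    lr = est[which]
    if lr is None or lr == 0 or not math.isfinite(lr):
        return None
    if which == "PLR":
        cells = (t.TP, t.FP)
    elif which == "NLR":
        cells = (t.FN, t.TN)
    else:
        raise ValueError("which must be 'PLR' or 'NLR'")
    if 0 in cells:
        return None
    a, b = cells
    se = math.sqrt(1 / a - 1 / t.n1 + 1 / b - 1 / t.n0)
    z = _z(level)
    return math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _inv_logit(x: float) -> float:
    return 1 / (1 + math.exp(-x))


def ci_pv(t: ConfusionTable, which: str, level: float = 0.95) -> tuple[float, float] | None:
    """Mercaldo logit-method CI for a predictive value (0–1 scale).

    var(logit PPV) = (1−sens)/(sens·n₁) + spec/((1−spec)·n₀)
    var(logit NPV) = sens/((1−sens)·n₁) + (1−spec)/(spec·n₀)

    A term whose numerator rate is 0 contributes nothing; a term whose
    denominator rate is 0 while the numerator is not makes the variance (and
    the CI) undefined.  A predictive value of exactly 0 or 1 has no logit and
    the CI is undefined (blank).
    """
    est = point_estimates(t)
    pv = est[which]
    sens, spec = est["sensitivity"], est["specificity"]
    if pv is None or sens is None or spec is None or pv in (0.0, 1.0):
        return None
    if which == "PPV":
        terms = [(1 - sens, sens * t.n1), (spec, (1 - spec) * t.n0)]
    elif which == "NPV":
        terms = [(sens, (1 - sens) * t.n1), (1 - spec, spec * t.n0)]
    else:
        raise ValueError("which must be 'PPV' or 'NPV'")
    var = 0.0
    for num, den in terms:
        if num == 0:
            continue
        if den == 0:
            return None
        var += num / den
    z = _z(level)
    half = z * math.sqrt(var)
    lg = _logit(pv)
    return _inv_logit(lg - half), _inv_logit(lg + half)


def percent_change(pair: ElisaPair) -> int | None:
    """Signed integer percent change end vs. begin; None when not computable.

    Undefined when the starting level is undetectable/missing/zero or the
    final level is missing.  Rounding is to the nearest integer, half away
    from zero.
    """
    if pair.begin is None or pair.begin == 0 or pair.end is None:
        return None
    frac = round(100.0 * (pair.end - pair.begin) / pair.begin, 9)  # absorb float fuzz
    return int(math.copysign(math.floor(abs(frac) + 0.5), frac))


_REPORT_SPEC = [
    # (name, percent scale, CI method)
    ("sensitivity", True, "clopper_pearson"),
    ("specificity", True, "clopper_pearson"),
    ("PLR", False, "simel_log"),
    ("NLR", False, "simel_log"),
    ("prevalence", True, "clopper_pearson"),
    ("PPV", True, "mercaldo_logit"),
    ("NPV", True, "mercaldo_logit"),
    ("accuracy", True, "clopper_pearson"),
]

_CP_CELLS = {
    "sensitivity": lambda t: (t.TP, t.n1),
    "specificity": lambda t: (t.TN, t.n0),
    "prevalence": lambda t: (t.n1, t.n),
    "accuracy": lambda t: (t.TP + t.TN, t.n),
}


def diagnostic_report(
    calls: Sequence[bool], truth: Sequence[bool], level: float = 0.95
) -> list[DiagnosticStat]:
    """Full screening-performance table from aligned per-subject records."""
    t = ConfusionTable.from_calls(calls, truth)
    return table_report(t, level=level)


def table_report(t: ConfusionTable, level: float = 0.95) -> list[DiagnosticStat]:
    est = point_estimates(t)
    out: list[DiagnosticStat] = []
    for name, percent, method in _REPORT_SPEC:
        value = est[name]
        ci: tuple[float, float] | None = None
        if value is not None:
            if method == "clopper_pearson":
                x, n = _CP_CELLS[name](t)
                if n > 0:
                    ci = ci_proportion_cp(x, n, level)
            elif method == "simel_log":
                ci = ci_lr(t, name, level)
            else:
                ci = ci_pv(t, name, level)
        scale = 100.0 if percent else 1.0
        out.append(
            DiagnosticStat(
                name=name,
                estimate=None if value is None else value * scale,
                ci_low=None if ci is None else ci[0] * scale,
                ci_high=None if ci is None else ci[1] * scale,
                method=method,
                percent=percent,
            )
        )
    return out


_DISPLAY_NAMES = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "PLR": "Positive likelihood ratio",
    "NLR": "Negative likelihood ratio",
    "prevalence": "Disease prevalence",
    "PPV": "Positive predictive value",
    "NPV": "Negative predictive value",
    "accuracy": "Accuracy",
}


def render_report(stats: list[DiagnosticStat]) -> pd.DataFrame:
    """Format a statistics list as a Statistic / Value / 95% CI table.

    Undefined estimates and CIs render as blank strings, matching the blank
    cells of clinical screening-performance tables.
    """
    rows = []
    for s in stats:
        if s.estimate is None:
            value = ""
        elif s.percent:
            value = f"{s.estimate:.2f}%"
        else:
            value = f"{s.estimate:.2f}"
        if s.ci_low is None:
            ci = ""
        elif s.percent:
            ci = f"From {s.ci_low:.2f} to {s.ci_high:.2f}%"
        else:
            ci = f"From {s.ci_low:.2f} to {s.ci_high:.2f}"
        rows.append({"Statistic": _DISPLAY_NAMES[s.name], "Value": value, "95% CI": ci})
    return pd.DataFrame(rows, columns=["Statistic", "Value", "95% CI"])
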