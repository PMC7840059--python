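"""Discrimination, accuracy, calibration and cohort summaries.

The validation battery for an external validation of a prognostic score on
administrative data:

* **c-statistic** (area under the ROC curve): probability that a randomly
  chosen death scored higher than a randomly chosen survivor, ties counted
  one half.  Computed by the Mann–Whitney rank formula, which is exactly the
  tie-corrected pairwise definition and equals the trapezoidal area under
  the ROC curve built by thresholding at every distinct score.
* **Brier score**: mean squared difference between predicted probability and
  the binary outcome.
* **Wald binomial confidence interval** for the cohort mortality proportion.
* **Calibration**: observed vs predicted mortality per integer score value,
  summarized by a least-squares line (slope 1, intercept 0 = perfect).
* **Cohort summary**: n, deaths, mortality with CI, score and age moments,
  per-sex strata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from ._rounding import round_half_up
from .cohort_filter import AttritionReport
from .score_table import RiskMap, predicted_risk
from .scoring_engine import PointDecomposition, ScoredCase


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given inputs (e.g. single-class outcomes)."""


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """ROC curve points (FPR, TPR) from (0,0) to (1,1) and its area."""

    points: tuple[tuple[float, float], ...]
    auc: float


def c_statistic(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Tie-corrected AUC: (concordant + 0.5 * tied) / (deaths * survivors).

    Uses the rank-sum identity; requires at least one death and one survivor.
    """
    y = np.asarray(outcomes, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("c-statistic undefined: need at least one death and one survivor")
    ranks = rankdata(s)  # mid-ranks handle ties = the 0.5 credit
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores: Sequence[float], outcomes: Sequence[bool]) -> RocCurve:
    """ROC built by thresholding at every distinct score (predict death iff
    score >= threshold); AUC by the trapezoid rule, which equals
    :func:`c_statistic` exactly for this construction."""
    y = np.asarray(outcomes, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("ROC undefined: need at least one death and one survivor")
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    for t in np.unique(s)[::-1]:  # descending thresholds
        pred = s >= t
        fpr = float((pred & ~y).sum() / n0)
        tpr = float((pred & y).sum() / n1)
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    arr = np.array(pts)
    auc = float(np.trapezoid(arr[:, 1], arr[:, 0]))
    return RocCurve(points=tuple(map(tuple, pts)), auc=auc)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def brier(predicted: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Mean squared difference between forecast probability and outcome."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise UndefinedStatisticError("Brier score undefined on empty input")
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald normal-approximation CI for a proportion, in percent.

    ``p ± z·sqrt(p(1−p)/n)``, reported as percentages rounded half-up to two
    decimals and clipped to [0, 100].
    """
    if n <= 0:
        raise UndefinedStatisticError("proportion CI undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    p = k / n
    z = float(norm.ppf(1 - (1 - level) / 2))
    half = z * math.sqrt(p * (1 - p) / n)
    lower = max(0.0, 100.0 * (p - half))
    upper = min(100.0, 100.0 * (p + half))
    return round_half_up(lower, 2), round_half_up(upper, 2)


# ---------------------------------------------------------------------------
# Calibration and per-score mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerScoreMortality:
    """Observed mortality at each integer score value present in the cohort.

    ``rows`` maps score -> (case count, death count, observed mortality in %).
    """

    rows: dict[int, tuple[int, int, float]]

    @property
    def total_cases(self) -> int:
        return sum(n for n, _, _ in self.rows.values())

    @property
    def total_deaths(self) -> int:
        return sum(d for _, d, _ in self.rows.values())

    def to_dict(self) -> dict:
        return {
            str(score): {"cases": n, "deaths": d, "mortality_pct": m}
            for score, (n, d, m) in sorted(self.rows.items())
        }


def per_score_mortality(cases: Sequence[ScoredCase]) -> PerScoreMortality:
    """Group by exact integer score; scores with no cases are omitted."""
    counts: dict[int, list[int]] = {}
    for c in cases:
        cell = counts.setdefault(c.score, [0, 0])
        cell[0] += 1
        cell[1] += int(c.outcome.died_in_hospital)
    rows = {
        s: (n, d, round_half_up(100.0 * d / n, 2))
        for s, (n, d) in sorted(counts.items())
    }
    return PerScoreMortality(rows=rows)


@dataclass(frozen=True)
class CalibrationFit:
    """Per-score (predicted, observed) calibration points and their LS line."""

    points: tuple[tuple[float, float, int], ...]  # (predicted, observed, cases)
    slope: float
    intercept: float
    weighting: str  # "none" | "cases" | "inverse_variance"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "weighting": self.weighting,
            "points": [
                {"predicted": p, "observed": o, "cases": n} for p, o, n in self.points
            ],
        }


def calibration_fit(
    per_score: PerScoreMortality,
    risk_map: RiskMap,
    weights: str | None = None,
) -> CalibrationFit:
    """Least-squares line through per-score (predicted, observed) points.

    One point per score value, exactly as a calibration plot draws them; the
    default is the unweighted fit over those dots.  ``weights="cases"``
    weights each dot by its case count; ``weights="inverse_variance"`` by
    ``n/(p(1-p))``, the efficient weighting when observed mortality in a
    score cell is binomial around the predicted value — appropriate when the
    fit is used to estimate the calibration slope rather than to annotate a
    figure.
    """
    pts = [
        (predicted_risk(score, risk_map), d / n if n else 0.0, n)
        for score, (n, d, _) in sorted(per_score.rows.items())
    ]
    x = np.array([p for p, _, _ in pts])
    y = np.array([o for _, o, _ in pts])
    n = np.array([c for _, _, c in pts], dtype=float)
    if np.unique(x).size < 2:
        raise UndefinedStatisticError("calibration fit undefined with < 2 distinct predicted values")
    if weights is None or weights == "none":
        w = np.ones_like(x)
        label = "none"
    elif weights == "cases":
        w = n
        label = "cases"
    elif weights == "inverse_variance":
        v = x * (1 - x)
        w = np.where(v > 0, n / np.where(v > 0, v, 1.0), n)
        label = "inverse_variance"
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    w = w / w.sum()
    xbar = float((w * x).sum())
    ybar = float((w * y).sum())
    sxx = float((w * (x - xbar) ** 2).sum())
    sxy = float((w * (x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    return CalibrationFit(points=tuple(pts), slope=slope, intercept=intercept, weighting=label)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexStratum:
    n: int
    pct: float
    mortality_pct: float
    mean_score: float
    mean_age: float
    median_age: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "pct": self.pct, "mortality_pct": self.mortality_pct,
            "mean_score": self.mean_score, "mean_age": self.mean_age,
            "median_age": self.median_age,
        }


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    n_deaths: int
    mortality_pct: float
    mortality_ci_pct: tuple[float, float]
    mean_score: float
    sd_score: float
    median_score: float
    mean_age: float
    sd_age: float
    median_age: float
    max_score: int
    strata: dict[str, SexStratum] = field(default_factory=dict)

    @property
    def stratum_sum_delta(self) -> int:
        """Total n minus the sum of stratum ns; nonzero values are reported,
        never silently reconciled."""
        return self.n_cases - sum(s.n for s in self.strata.values())

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_deaths": self.n_deaths,
            "mortality_pct": self.mortality_pct,
            "mortality_ci_pct": list(self.mortality_ci_pct),
            "mean_score": self.mean_score,
            "sd_score": self.sd_score,
            "median_score": self.median_score,
            "mean_age": self.mean_age,
            "sd_age": self.sd_age,
            "median_age": self.median_age,
            "max_score": self.max_score,
            "strata": {k: v.to_dict() for k, v in sorted(self.strata.items())},
            "stratum_sum_delta": self.stratum_sum_delta,
        }


def _sd(values: np.ndarray) -> float:
    # sample SD (n-1 denominator); 0 for a single observation
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def summarize_cohort(cases: Sequence[ScoredCase], ci_level: float = 0.95) -> CohortSummary:
    """Headline cohort statistics at full precision (rounding at report time).

    Mean/SD use the sample (n−1) convention; medians use numpy's midpoint
    convention for even n.
    """
    if not cases:
        raise UndefinedStatisticError("cohort summary undefined on empty cohort")
    scores = np.array([c.score for c in cases], dtype=float)
    ages = np.array([c.case.age for c in cases], dtype=float)
    deaths = sum(c.outcome.died_in_hospital for c in cases)
    n = len(cases)
    strata: dict[str, SexStratum] = {}
    for sex in sorted({c.case.sex for c in cases}):
        sub = [c for c in cases if c.case.sex == sex]
        sub_scores = np.array([c.score for c in sub], dtype=float)
        sub_ages = np.array([c.case.age for c in sub], dtype=float)
        sub_deaths = sum(c.outcome.died_in_hospital for c in sub)
        strata[sex] = SexStratum(
            n=len(sub),
            pct=round_half_up(100.0 * len(sub) / n, 2),
            mortality_pct=round_half_up(100.0 * sub_deaths / len(sub), 2),
            mean_score=float(sub_scores.mean()),
            mean_age=float(sub_ages.mean()),
            median_age=float(np.median(sub_ages)),
        )
    return CohortSummary(
        n_cases=n,
        n_deaths=int(deaths),
        mortality_pct=round_half_up(100.0 * deaths / n, 2),
        mortality_ci_pct=proportion_ci(int(deaths), n, ci_level),
        mean_score=float(scores.mean()),
        sd_score=_sd(scores),
        median_score=float(np.median(scores)),
        mean_age=float(ages.mean()),
        sd_age=_sd(ages),
        median_age=float(np.median(ages)),
        max_score=int(scores.max()),
        strata=strata,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    summary: CohortSummary
    decomposition: PointDecomposition
    auc: float | None
    brier: float | None
    calibration: CalibrationFit | None
    per_score: PerScoreMortality
    attrition: AttritionReport | None = None

    def to_dict(self) -> dict:
        return {
            "summary": self.summary.to_dict(),
            "attrition": None if self.attrition is None else self.attrition.to_dict(),
            "point_decomposition": self.decomposition.to_dict(),
            "auc": self.auc,
            "brier": self.brier,
            "calibration": None if self.calibration is None else self.calibration.to_dict(),
            "per_score_mortality": self.per_score.to_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def build_validation_report(
    cases: Sequence[ScoredCase],
    risk_map: RiskMap | None = None,
    attrition: AttritionReport | None = None,
    ci_level: float = 0.95,
    calibration_weights: str | None = None,
) -> ValidationReport:
    """Run the full battery on a scored cohort.

    Single-class cohorts (no deaths, or no survivors) yield a report with the
    AUC marked undefined (``None``) rather than an error.
    """
    from .scoring_engine import decompose_points

    summary = summarize_cohort(cases, ci_level)
    scores = [c.score for c in cases]
    outcomes = [c.outcome.died_in_hospital for c in cases]
    try:
        auc = c_statistic(scores, outcomes)
    except UndefinedStatisticError:
        auc = None
    per_score = per_score_mortality(cases)
    brier_score = None
    cal = None
    if risk_map is not None:
        preds = [
            c.predicted_risk if c.predicted_risk is not None else predicted_risk(c.score, risk_map)
            for c in cases
        ]
        brier_score = brier(preds, outcomes)
        try:
            cal = calibration_fit(per_score, risk_map, weights=calibration_weights)
        except UndefinedStatisticError:
            cal = None
    return ValidationReport(
        summary=summary,
        decomposition=decompose_points(cases),
        auc=auc,
        brier=brier_score,
        calibration=cal,
        per_score=per_score,
        attrition=attrition,
    )
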