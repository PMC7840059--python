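"""Score computation: per-case point assignment and cohort decomposition.

A case's score is the exact integer sum of three components:

* **age points** — the points of the unique age band containing the age;
* **comorbidity points** — each comorbidity group contributes its points at
  most once, iff any diagnosis code matches any of its prefixes;
* **surgery points** — the points of the assigned index surgery: among
  matching procedures the chronologically first is taken; among procedures
  tied on the earliest date (or with no dates at all) the group worth the
  most points wins, with a final deterministic lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .registry_io import CaseRecord, DEFAULT_DEATH_CODES, Outcome, derive_outcome
from .score_table import PointTable, RiskMap, SurgeryGroup, predicted_risk
from ._rounding import round_half_up


@dataclass
class ScoredCase:
    """A case plus its score decomposition and outcome."""

    case: CaseRecord
    age_points: int
    comorbidity_points: int
    surgery_points: int
    score: int
    matched_comorbidities: list[str]
    surgery_group: str
    outcome: Outcome
    predicted_risk: float | None = None


@dataclass(frozen=True)
class PointDecomposition:
    """Cohort-level totals of applied points and their percentage shares."""

    total_points: int
    comorbidity_points_total: int
    age_points_total: int
    surgery_points_total: int
    comorbidity_share_pct: float
    age_share_pct: float
    surgery_share_pct: float

    def to_dict(self) -> dict:
        return {
            "total_points": self.total_points,
            "comorbidity_points_total": self.comorbidity_points_total,
            "age_points_total": self.age_points_total,
            "surgery_points_total": self.surgery_points_total,
            "comorbidity_share_pct": self.comorbidity_share_pct,
            "age_share_pct": self.age_share_pct,
            "surgery_share_pct": self.surgery_share_pct,
        }


def age_points(age: int, table: PointTable) -> int:
    """Points of the unique age band containing ``age`` (age >= 18 expected)."""
    if age < 18:
        raise ValueError(f"age {age} below adult minimum; eligibility filter should have excluded it")
    return table.age_band_for(age).points


def comorbidity_points(case: CaseRecord, table: PointTable) -> tuple[int, list[str]]:
    """Sum of points of every comorbidity group matched by the case's codes.

    A group scores at most once regardless of how many of its codes a case
    carries, so duplicated codes never change the score.
    """
    points = 0
    matched: list[str] = []
    codes = case.icd_codes
    for group in table.comorbidities:
        if group.icd_prefixes and any(c.startswith(group.icd_prefixes) for c in codes):
            points += group.points
            matched.append(group.name)
    return points, matched


def select_surgery(case: CaseRecord, table: PointTable) -> tuple[SurgeryGroup, int]:
    """Assign the index surgery: earliest date first, then maximum points.

    Chronology beats point value; the max-points rule applies only among
    procedures tied on the earliest date (procedures without dates are
    treated as simultaneous, and sort after dated ones).  Residual ties
    (same date, same points, different groups) break lexicographically by
    group name for determinism.
    """
    candidates: list[tuple] = []  # (date_key, -points, name, group)
    for code, date in case.procedures:
        for group in table.surgeries:
            if group.matches_code(code):
                date_key = (1, 0) if date is None else (0, date.toordinal())
                candidates.append((date_key, -group.points, group.name, group))
                break  # validator guarantees at most one group per code
    if not candidates:
        raise ValueError(f"case {case.case_id!r} has no index procedure; eligibility filter should have excluded it")
    # earliest date; among ties the highest points; then name
    group = min(candidates, key=lambda t: t[:3])[3]
    return group, group.points


def score_case(
    case: CaseRecord,
    table: PointTable,
    risk_map: RiskMap | None = None,
    death_codes: frozenset[str] = DEFAULT_DEATH_CODES,
) -> ScoredCase:
    """Compute the full score decomposition for one eligible case."""
    ap = age_points(case.age, table)
    cp, matched = comorbidity_points(case, table)
    group, sp = select_surgery(case, table)
    score = ap + cp + sp
    return ScoredCase(
        case=case,
        age_points=ap,
        comorbidity_points=cp,
        surgery_points=sp,
        score=score,
        matched_comorbidities=matched,
        surgery_group=group.name,
        outcome=derive_outcome(case, death_codes),
        predicted_risk=None if risk_map is None else predicted_risk(score, risk_map),
    )


def score_cohort(
    cases: Sequence[CaseRecord],
    table: PointTable,
    risk_map: RiskMap | None = None,
    death_codes: frozenset[str] = DEFAULT_DEATH_CODES,
) -> list[ScoredCase]:
    return [score_case(c, table, risk_map, death_codes) for c in cases]


def decompose_points(cases: Sequence[ScoredCase]) -> PointDecomposition:
    """Cohort totals per component and their shares of all applied points.

    Shares are percentages rounded half-up to 2 decimals; an empty or
    all-zero cohort has all shares defined as 0.
    """
    cp = sum(c.comorbidity_points for c in cases)
    ap = sum(c.age_points for c in cases)
    sp = sum(c.surgery_points for c in cases)
    total = cp + ap + sp
    if total == 0:
        shares = (0.0, 0.0, 0.0)
    else:
        shares = tuple(round_half_up(100.0 * x / total, 2) for x in (cp, ap, sp))
    return PointDecomposition(
        total_points=total,
        comorbidity_points_total=cp,
        age_points_total=ap,
        surgery_points_total=sp,
        comorbidity_share_pct=shares[0],
        age_share_pct=shares[1],
        surgery_share_pct=shares[2],
    )
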