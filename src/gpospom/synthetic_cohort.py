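"""Synthetic registry generation with exact control of the score distribution.

Real §21 KHEntgG extracts cannot be redistributed, so the validation pipeline
is exercised on synthetic registries.  Two generators are provided:

* :func:`generate_fixture` — an attrition fixture: exact stratum counts for
  the eligibility cascade (cases without an index procedure, minors,
  incomplete records, eligible cases with an exact number of deaths), for
  testing the flow-chart accounting at full registry scale.
* :func:`generate_statistical` — a statistical cohort: integer scores drawn
  from a truncated discretized normal, case codes constructed by *inverse
  construction* so each case scores exactly its drawn value under the
  scoring engine, and in-hospital death simulated from a logistic (or
  tabulated) score→mortality link.  Because the generating link is known,
  calibration-slope and AUC recovery can be checked against ground truth.

Scores are generated first and codes built to match, rather than sampling
codes and accepting the resulting score: the validation battery consumes the
score distribution, so that is what the generator controls exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .registry_io import CaseRecord
from .score_table import PointTable, RiskMap, predicted_risk

#: Default score distribution of the statistical generator: the score mean and
#: SD of a large German university-hospital surgical cohort (mean 18.18,
#: SD 8.11 score points).
DEFAULT_SCORE_MEAN = 18.18
DEFAULT_SCORE_SD = 8.11
#: Default female share of cases in the same cohort.
DEFAULT_FEMALE_SHARE = 0.4924

#: Default attrition strata (input total; no index procedure; minors;
#: incomplete; deaths among the included), sized like a 12-year single-centre
#: extract.
DEFAULT_FIXTURE_STRATA = dict(
    n_total=357_861,
    n_without_index=115_281,
    n_minor=41_836,
    n_incomplete=964,
    n_deaths_among_included=4_053,
)


class UnattainableScoreError(ValueError):
    def __init__(self, target: int, attainable: Sequence[int]):
        arr = np.asarray(sorted(attainable))
        dist = np.abs(arr - target)
        near = sorted(int(s) for s in arr[dist == dist.min()])
        super().__init__(
            f"score {target} is not attainable under this point table; "
            f"nearest attainable scores: {near}"
        )
        self.target = target
        self.nearest = near


# ---------------------------------------------------------------------------
# Attainability and inverse construction
# ---------------------------------------------------------------------------

class _Decomposer:
    """Per-table caches: comorbidity subset-sum DP and (age, surgery) combos."""

    def __init__(self, table: PointTable):
        self.table = table
        pts = [g.points for g in table.comorbidities]
        total = sum(pts)
        # suffix attainability: reach[i][v] == True iff v is a subset sum of pts[i:]
        reach = np.zeros((len(pts) + 1, total + 1), dtype=bool)
        reach[len(pts)][0] = True
        for i in range(len(pts) - 1, -1, -1):
            reach[i] = reach[i + 1].copy()
            p = pts[i]
            if p:  # a zero-point group adds no new sums
                reach[i][p:] |= reach[i + 1][: total + 1 - p]
        self.reach = reach
        self.comorb_points = pts
        self.pairs = [
            (band, group)
            for band in table.age_bands
            for group in table.surgeries
        ]
        comorb_sums = np.flatnonzero(reach[0])
        scores = {
            band.points + group.points + int(s)
            for band, group in self.pairs
            for s in comorb_sums
        }
        self.attainable = np.array(sorted(scores), dtype=int)

    def pairs_for(self, target: int) -> list:
        """(age band, surgery group) combos leaving an attainable remainder."""
        out = []
        for band, group in self.pairs:
            r = target - band.points - group.points
            if 0 <= r < self.reach.shape[1] and self.reach[0][r]:
                out.append((band, group, r))
        return out

    def comorb_subset(self, remainder: int, rng: np.random.Generator) -> list[int]:
        """Random subset of comorbidity-group indices summing to ``remainder``."""
        chosen: list[int] = []
        r = remainder
        for i, p in enumerate(self.comorb_points):
            can_skip = self.reach[i + 1][r]
            can_take = p <= r and self.reach[i + 1][r - p]
            if can_take and (not can_skip or rng.random() < 0.5):
                chosen.append(i)
                r -= p
            elif not can_skip:
                raise AssertionError("subset-sum backtrack dead end")  # pragma: no cover
        assert r == 0
        return chosen


_DECOMPOSER_CACHE: dict[int, _Decomposer] = {}


def _decomposer(table: PointTable) -> _Decomposer:
    key = id(table)
    dec = _DECOMPOSER_CACHE.get(key)
    if dec is None or dec.table is not table:
        dec = _Decomposer(table)
        _DECOMPOSER_CACHE[key] = dec
    return dec


def attainable_scores(table: PointTable) -> list[int]:
    """All integer scores reachable by some (age, comorbidity set, surgery)."""
    return _decomposer(table).attainable.tolist()


def _sample_age(band, rng: np.random.Generator) -> int:
    upper = band.upper_age if band.upper_age is not None else max(band.lower_age + 14, 100)
    return int(rng.integers(band.lower_age, upper + 1))


def codes_for_score(
    target: int,
    table: PointTable,
    rng: np.random.Generator,
) -> tuple[int, list[str], list[str]]:
    """Inverse construction: (age, ICD codes, OPS codes) scoring exactly ``target``.

    Picks, uniformly at random among valid combinations, one age band, one
    surgery group and a comorbidity subset whose points sum to the target;
    concrete codes are the groups' first-listed prefixes (a prefix is itself
    a valid code).  Raises :class:`UnattainableScoreError` with the nearest
    attainable scores otherwise.
    """
    dec = _decomposer(table)
    options = dec.pairs_for(int(target))
    if not options:
        raise UnattainableScoreError(int(target), dec.attainable)
    band, group, remainder = options[int(rng.integers(len(options)))]
    comorb_idx = dec.comorb_subset(remainder, rng)
    age = _sample_age(band, rng)
    icd = [table.comorbidities[i].icd_prefixes[0] for i in comorb_idx]
    ops = [group.ops_prefixes[0]]
    return age, icd, ops


def nearest_attainable(values: np.ndarray, attainable: np.ndarray) -> np.ndarray:
    """Map continuous draws to the nearest attainable score, ties upward."""
    idx = np.searchsorted(attainable, values)
    idx = np.clip(idx, 1, len(attainable) - 1)
    lo = attainable[idx - 1]
    hi = attainable[idx]
    # tie (equidistant) -> upper
    take_hi = (hi - values) <= (values - lo)
    out = np.where(take_hi, hi, lo)
    out[values <= attainable[0]] = attainable[0]
    out[values >= attainable[-1]] = attainable[-1]
    return out


def _draw_scores(
    n: int,
    mean: float,
    sd: float,
    attainable: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = float(attainable[0]), float(attainable[-1])
    if sd == 0:
        target = nearest_attainable(np.full(n, mean), attainable)
        return target.astype(int)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return nearest_attainable(draws, attainable).astype(int)


# ---------------------------------------------------------------------------
# Fixture generator (exact attrition strata)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Exact stratum sizes for an attrition fixture."""

    n_total: int = DEFAULT_FIXTURE_STRATA["n_total"]
    n_without_index: int = DEFAULT_FIXTURE_STRATA["n_without_index"]
    n_minor: int = DEFAULT_FIXTURE_STRATA["n_minor"]
    n_incomplete: int = DEFAULT_FIXTURE_STRATA["n_incomplete"]
    n_deaths_among_included: int = DEFAULT_FIXTURE_STRATA["n_deaths_among_included"]
    seed: int = 0

    def __post_init__(self):
        strata = self.n_without_index + self.n_minor + self.n_incomplete
        if min(self.n_total, self.n_without_index, self.n_minor, self.n_incomplete,
               self.n_deaths_among_included, self.seed) < 0:
            raise ValueError("fixture spec counts must be non-negative")
        if strata > self.n_total:
            raise ValueError(
                f"excluded strata ({strata}) exceed n_total ({self.n_total})"
            )
        if self.n_deaths_among_included > self.n_total - strata:
            raise ValueError("more deaths than eligible cases")

    @property
    def n_eligible(self) -> int:
        return self.n_total - self.n_without_index - self.n_minor - self.n_incomplete


#: A procedure code outside every surgical chapter prefix of the demo tables
#: (diagnostic chapter), used for the "no index procedure" stratum.
_NON_INDEX_OPS = "1-999"


def generate_fixture(
    spec: FixtureSpec,
    table: PointTable,
    score_mean: float = DEFAULT_SCORE_MEAN,
    score_sd: float = DEFAULT_SCORE_SD,
    female_share: float = DEFAULT_FEMALE_SHARE,
) -> list[CaseRecord]:
    """Registry with exactly the requested attrition strata, shuffled.

    Eligible cases carry scores drawn from the truncated discretized normal
    and exactly ``n_deaths_among_included`` death dispositions.  Deterministic
    given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    dec = _decomposer(table)
    cases: list[CaseRecord] = []

    # the non-index code must really not match
    if any(_NON_INDEX_OPS.startswith(g.ops_prefixes) for g in table.surgeries):
        raise ValueError("demo non-index code collides with a surgery prefix of this table")

    for i in range(spec.n_without_index):
        cases.append(CaseRecord(
            case_id="", age=int(rng.integers(18, 95)), sex="female" if rng.random() < female_share else "male",
            icd_codes=[], procedures=[(_NON_INDEX_OPS, None)], discharge_reason="01",
        ))
    some_surgery = table.surgeries[0].ops_prefixes[0]
    for i in range(spec.n_minor):
        cases.append(CaseRecord(
            case_id="", age=int(rng.integers(0, 18)), sex="female" if rng.random() < female_share else "male",
            icd_codes=[], procedures=[(some_surgery, None)], discharge_reason="01",
        ))
    for i in range(spec.n_incomplete):
        missing_age = rng.random() < 0.5
        cases.append(CaseRecord(
            case_id="",
            age=None if missing_age else int(rng.integers(18, 95)),
            sex="female" if rng.random() < female_share else "male",
            icd_codes=[], procedures=[(some_surgery, None)],
            discharge_reason="01" if missing_age else None,
        ))

    n_elig = spec.n_eligible
    scores = _draw_scores(n_elig, score_mean, score_sd, dec.attainable, rng)
    died = np.zeros(n_elig, dtype=bool)
    if spec.n_deaths_among_included:
        died[rng.choice(n_elig, size=spec.n_deaths_among_included, replace=False)] = True
    # one cached random decomposition per score value keeps generation O(n)
    decomp_cache: dict[int, tuple] = {}
    sex_draw = rng.random(n_elig)
    for i in range(n_elig):
        s = int(scores[i])
        cached = decomp_cache.get(s)
        if cached is None:
            options = dec.pairs_for(s)
            band, group, remainder = options[int(rng.integers(len(options)))]
            comorb_idx = dec.comorb_subset(remainder, rng)
            icd = [table.comorbidities[j].icd_prefixes[0] for j in comorb_idx]
            ops = group.ops_prefixes[0]
            cached = (band, icd, ops)
            decomp_cache[s] = cached
        band, icd, ops = cached
        cases.append(CaseRecord(
            case_id="",
            age=_sample_age(band, rng),
            sex="female" if sex_draw[i] < female_share else "male",
            icd_codes=list(icd),
            procedures=[(ops, None)],
            discharge_reason="07" if died[i] else "01",
        ))

    rng.shuffle(cases)  # interleave strata like a real extract
    for i, c in enumerate(cases):
        c.case_id = f"C{i + 1:07d}"
    return cases


# ---------------------------------------------------------------------------
# Statistical generator (known score distribution and outcome link)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Statistical cohort: score distribution plus score→mortality link."""

    n: int
    score_mean: float = DEFAULT_SCORE_MEAN
    score_sd: float = DEFAULT_SCORE_SD
    female_share: float = DEFAULT_FEMALE_SHARE
    seed: int = 0

    def __post_init__(self):
        if self.n < 0 or self.score_sd < 0 or not 0 <= self.female_share <= 1:
            raise ValueError(f"invalid cohort spec: {self}")


def generate_statistical(
    spec: CohortSpec,
    table: PointTable,
    link: RiskMap,
    return_truth: bool = False,
):
    """Cohort of ``spec.n`` eligible cases with a known data-generating process.

    Scores are drawn from the truncated discretized normal (bounds = the
    attainable range of the table, nearest-attainable rounding with ties up),
    codes are inverse-constructed per case, and death is Bernoulli in the
    link's predicted probability at the case's score.  With
    ``return_truth=True`` also returns the intended scores and generating
    probabilities for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    dec = _decomposer(table)
    scores = _draw_scores(spec.n, spec.score_mean, spec.score_sd, dec.attainable, rng)
    probs = np.array([predicted_risk(int(s), link) for s in np.unique(scores)])
    prob_of = dict(zip(np.unique(scores).tolist(), probs.tolist()))
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("outcome link produced probabilities outside [0, 1]")
    death_draw = rng.random(spec.n)
    sex_draw = rng.random(spec.n)
    cases: list[CaseRecord] = []
    p_vec = np.empty(spec.n)
    for i in range(spec.n):
        s = int(scores[i])
        age, icd, ops = codes_for_score(s, table, rng)
        p = prob_of[s]
        p_vec[i] = p
        cases.append(CaseRecord(
            case_id=f"S{i + 1:07d}",
            age=age,
            sex="female" if sex_draw[i] < spec.female_share else "male",
            icd_codes=icd,
            procedures=[(c, None) for c in ops],
            discharge_reason="07" if death_draw[i] < p else "01",
        ))
    if return_truth:
        return cases, scores.astype(int), p_vec
    return cases


def score_distribution(
    mean: float,
    sd: float,
    table: PointTable,
) -> dict[int, float]:
    """Exact probability mass of the truncated discretized normal over the
    attainable scores of ``table``.

    This is the distribution :func:`generate_statistical` draws from: a
    normal truncated to the attainable range, then rounded to the nearest
    attainable score (ties up), i.e. the mass at score ``s`` is the truncated
    normal's probability of the midpoint interval around ``s``.  Useful as
    the analytic oracle for moments of simulated cohorts — note its mean is
    *not* the input ``mean`` when the truncation is asymmetric.
    """
    att = _decomposer(table).attainable.astype(float)
    lo, hi = att[0], att[-1]
    if sd == 0:
        target = int(nearest_attainable(np.array([mean]), att.astype(int))[0])
        return {target: 1.0}
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = truncnorm(a, b, loc=mean, scale=sd)
    # interval around each attainable score: [mid(prev, s), mid(s, next));
    # "ties up" puts the midpoint itself in the upper cell, a measure-zero
    # distinction for the continuous draw
    mids = (att[:-1] + att[1:]) / 2.0
    edges = np.concatenate([[lo], mids, [hi]])
    cdf = dist.cdf(edges)
    mass = np.diff(cdf)
    mass[0] += cdf[0]  # mass exactly at the lower bound
    mass = mass / mass.sum()
    return {int(s): float(m) for s, m in zip(att, mass)}


def expected_auc(score_counts: dict[int, int], link: RiskMap) -> float:
    """Ground-truth AUC implied by a score distribution and an outcome link.

    Treats each score cell as contributing ``n_s * p_s`` expected deaths and
    ``n_s * (1 - p_s)`` expected survivors and evaluates the pairwise
    concordance (ties half) in closed form — the oracle a simulated cohort's
    empirical c-statistic should approach.
    """
    scores = np.array(sorted(score_counts))
    ns = np.array([score_counts[int(s)] for s in scores], dtype=float)
    ps = np.array([predicted_risk(int(s), link) for s in scores])
    wd = ns * ps
    ws = ns * (1 - ps)
    cum_ws = np.concatenate([[0.0], np.cumsum(ws)])
    num = float(np.sum(wd * (cum_ws[:-1] + 0.5 * ws)))
    denom = float(wd.sum() * ws.sum())
    if denom == 0:
        raise ValueError("degenerate link: no expected deaths or no expected survivors")
    return num / denom
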