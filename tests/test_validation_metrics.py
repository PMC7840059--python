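"""Discrimination, accuracy, calibration and cohort-summary statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpospom import (
    CohortSummary,
    Outcome,
    RiskMap,
    ScoredCase,
    UndefinedStatisticError,
    brier,
    build_validation_report,
    c_statistic,
    calibration_fit,
    per_score_mortality,
    proportion_ci,
    roc_curve,
    summarize_cohort,
)
from gpospom.validation_metrics import SexStratum
from conftest import make_case


def _scored(score: int, died: bool, sex: str = "female", age: int = 50,
            predicted: float | None = None) -> ScoredCase:
    return ScoredCase(
        case=make_case(age=age, sex=sex), age_points=0, comorbidity_points=0,
        surgery_points=score, score=score, matched_comorbidities=[],
        surgery_group="g", outcome=Outcome(died), predicted_risk=predicted,
    )


def _pairwise_auc(scores, outcomes) -> float:
    deaths = [s for s, o in zip(scores, outcomes) if o]
    survivors = [s for s, o in zip(scores, outcomes) if not o]
    num = sum(1.0 if d > s else 0.5 if d == s else 0.0 for d in deaths for s in survivors)
    return num / (len(deaths) * len(survivors))


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([1, 2, 3], [False, False, True]) == 1.0

    def test_all_ties_is_chance(self):
        assert c_statistic([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_hand_enumerated_pairs(self):
        # death-survivor pairs: (2,1)+, (2,2) half, (3,1)+, (3,2)+ -> 3.5/4
        assert c_statistic([1, 2, 2, 3], [False, True, False, True]) == 0.875

    def test_single_class_raises(self):
        with pytest.raises(UndefinedStatisticError):
            c_statistic([1, 2], [False, False])

    @settings(max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 30), st.booleans()), min_size=2, max_size=200))
    def test_matches_pairwise_oracle(self, pairs):
        scores = [s for s, _ in pairs]
        outcomes = [o for _, o in pairs]
        if all(outcomes) or not any(outcomes):
            return
        assert c_statistic(scores, outcomes) == pytest.approx(
            _pairwise_auc(scores, outcomes), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 40, size=150)
        outcomes = rng.random(150) < 0.3
        if not outcomes.any() or outcomes.all():
            pytest.skip("degenerate draw")
        a = c_statistic(scores, outcomes)
        b = c_statistic(np.exp(scores / 10.0), outcomes)
        assert a == pytest.approx(b, abs=1e-12)

    def test_complementing_outcomes_reflects_auc(self):
        rng = np.random.default_rng(10)
        scores = rng.integers(0, 40, size=150)
        outcomes = rng.random(150) < 0.3
        assert c_statistic(scores, outcomes) == pytest.approx(
            1.0 - c_statistic(scores, ~outcomes), abs=1e-12)

    def test_roc_trapezoid_equals_rank_formula(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 25, size=300)
        outcomes = rng.random(300) < (scores / 50.0)
        curve = roc_curve(scores, outcomes)
        assert curve.auc == pytest.approx(c_statistic(scores, outcomes), abs=1e-12)
        fpr = [p[0] for p in curve.points]
        tpr = [p[1] for p in curve.points]
        assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)
        assert all(a <= b + 1e-15 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(tpr, tpr[1:]))

    def test_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 40, size=500)
        outcomes = rng.random(500) < 0.15
        assert c_statistic(scores, outcomes) == pytest.approx(
            sklearn.roc_auc_score(outcomes, scores), abs=1e-12)


class TestBrier:
    def test_perfect_forecasts(self):
        assert brier([0.0, 1.0, 0.0], [False, True, False]) == 0.0

    def test_hand_computed(self):
        assert brier([0.2, 0.8], [False, True]) == pytest.approx(0.04, abs=1e-15)

    def test_constant_prevalence_forecast_identity(self):
        outcomes = [True] * 3 + [False] * 7
        p = 0.3
        assert brier([p] * 10, outcomes) == pytest.approx(p * (1 - p), abs=1e-15)

    def test_empty_raises(self):
        with pytest.raises(UndefinedStatisticError):
            brier([], [])

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [True])


class TestProportionCI:
    def test_zero_deaths_clipped_at_zero(self):
        lo, hi = proportion_ci(0, 100)
        assert lo == 0.0 and hi >= 0.0

    def test_reproduces_published_mortality_interval(self):
        assert proportion_ci(4_053, 199_780) == (1.97, 2.09)

    def test_symmetric_about_half(self):
        lo, hi = proportion_ci(5_000, 10_000)
        assert lo + hi == pytest.approx(100.0, abs=1e-9)

    def test_width_scales_as_inverse_sqrt_n(self):
        widths = []
        for n in (10**3, 10**4, 10**5):
            k = n // 20
            lo, hi = proportion_ci(k, n)
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(np.sqrt(10), rel=0.05)
        assert widths[1] / widths[2] == pytest.approx(np.sqrt(10), rel=0.05)

    def test_n_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            proportion_ci(0, 0)


class TestPerScoreMortality:
    def test_half_mortality_cell(self):
        table = per_score_mortality([_scored(10, True), _scored(10, False)])
        assert table.rows == {10: (2, 1, 50.0)}

    def test_empty_input(self):
        assert per_score_mortality([]).rows == {}

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(13)
        cases = [_scored(int(s), bool(d))
                 for s, d in zip(rng.integers(0, 20, 400), rng.random(400) < 0.2)]
        table = per_score_mortality(cases)
        for s in {c.score for c in cases}:
            sub = [c for c in cases if c.score == s]
            deaths = sum(c.outcome.died_in_hospital for c in sub)
            assert table.rows[s][0] == len(sub)
            assert table.rows[s][1] == deaths
        assert table.total_cases == 400


class TestCalibrationFit:
    def test_perfect_calibration_recovers_identity(self):
        m = RiskMap(mode="table", table={0: 0.1, 1: 0.2, 2: 0.4})
        cases = []
        for score, p in [(0, 0.1), (1, 0.2), (2, 0.4)]:
            n = 10
            k = int(round(p * n))
            cases += [_scored(score, True)] * k + [_scored(score, False)] * (n - k)
        fit = calibration_fit(per_score_mortality(cases), m)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_flat_observed_gives_zero_slope(self):
        m = RiskMap(mode="table", table={0: 0.1, 1: 0.3})
        cases = ([_scored(0, True)] + [_scored(0, False)] * 4
                 + [_scored(1, True)] + [_scored(1, False)] * 4)
        fit = calibration_fit(per_score_mortality(cases), m)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.2, abs=1e-12)

    def test_five_points_match_closed_form_ols(self):
        # per-score cells engineered to give exact observed proportions
        xs = [0.05, 0.10, 0.20, 0.30, 0.50]
        ys = [0.0, 0.2, 0.1, 0.4, 0.5]
        m = RiskMap(mode="table", table={i: x for i, x in enumerate(xs)})
        cases = []
        for i, y in enumerate(ys):
            k = int(round(y * 10))
            cases += [_scored(i, True)] * k + [_scored(i, False)] * (10 - k)
        fit = calibration_fit(per_score_mortality(cases), m)
        x, y = np.array(xs), np.array(ys)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_single_point_undefined(self):
        m = RiskMap(mode="table", table={0: 0.1})
        with pytest.raises(UndefinedStatisticError):
            calibration_fit(per_score_mortality([_scored(0, False)]), m)

    def test_case_weighting_shifts_toward_large_cells(self):
        m = RiskMap(mode="table", table={0: 0.1, 1: 0.2, 2: 0.9})
        # tiny badly-calibrated high-risk cell, large well-calibrated cells
        cases = ([_scored(0, True)] + [_scored(0, False)] * 9) * 20
        cases += ([_scored(1, True)] * 2 + [_scored(1, False)] * 8) * 20
        cases += [_scored(2, False)]  # observed 0 at predicted 0.9
        psm = per_score_mortality(cases)
        unweighted = calibration_fit(psm, m)
        weighted = calibration_fit(psm, m, weights="cases")
        assert abs(weighted.slope - 1.0) < abs(unweighted.slope - 1.0)


class TestSummarizeCohort:
    def test_single_case(self):
        s = summarize_cohort([_scored(7, False)])
        assert s.mean_score == 7 and s.sd_score == 0.0 and s.mortality_pct == 0.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            summarize_cohort([])

    def test_counts_and_strata(self):
        cases = [
            _scored(10, False, sex="female", age=40),
            _scored(20, True, sex="female", age=60),
            _scored(30, False, sex="male", age=50),
            _scored(40, True, sex="male", age=70),
        ]
        s = summarize_cohort(cases)
        assert s.n_cases == 4 and s.n_deaths == 2 and s.mortality_pct == 50.0
        assert s.median_score == 25.0  # midpoint convention, even n
        assert s.strata["female"].n == 2 and s.strata["male"].n == 2
        assert s.stratum_sum_delta == 0
        assert s.max_score == 40

    def test_sample_sd_convention(self):
        s = summarize_cohort([_scored(10, False), _scored(20, False)])
        assert s.sd_score == pytest.approx(np.std([10, 20], ddof=1), abs=1e-12)

    def test_stratum_sum_mismatch_is_reported_not_fixed(self):
        # published-style aggregates where strata fall 10 cases short
        stratum = SexStratum(n=98_376, pct=49.24, mortality_pct=1.73,
                             mean_score=16.96, mean_age=54.25, median_age=55.0)
        stratum_m = SexStratum(n=101_394, pct=50.75, mortality_pct=2.33,
                               mean_score=19.35, mean_age=58.38, median_age=61.0)
        s = CohortSummary(
            n_cases=199_780, n_deaths=4_053, mortality_pct=2.03,
            mortality_ci_pct=(1.97, 2.09), mean_score=18.18, sd_score=8.11,
            median_score=18.0, mean_age=56.33, sd_age=18.59, median_age=59.0,
            max_score=49, strata={"female": stratum, "male": stratum_m},
        )
        assert s.stratum_sum_delta == 10
        assert s.to_dict()["stratum_sum_delta"] == 10


class TestReportAssembly:
    def test_single_class_cohort_reports_undefined_auc(self, demo_link):
        cases = [_scored(s, False, predicted=0.1) for s in (1, 2, 3)]
        report = build_validation_report(cases, demo_link)
        assert report.auc is None
        assert report.brier is not None

    def test_report_json_is_stable(self, demo_link, tmp_path):
        cases = [_scored(1, False, predicted=0.01), _scored(2, True, predicted=0.02),
                 _scored(2, False, predicted=0.02)]
        report = build_validation_report(cases, demo_link)
        a = report.to_json(tmp_path / "r.json")
        b = build_validation_report(cases, demo_link).to_json()
        assert a == b
        assert (tmp_path / "r.json").read_text().strip() == a.strip()
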