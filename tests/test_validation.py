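import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import brentq

from aecase.validation import (
    DegenerateTableError,
    LabelledOutcome,
    as_percent,
    bland_altman,
    compare_proportions,
    detection_fraction,
    ppv,
    rank_sum,
    validate_cohort,
)

# printed Table-3-style study counts: (variant, TP, positives, PPV %)
STUDY_COUNTS = [
    ("baseline", 163, 189, 86),
    ("steroid1", 157, 183, 86),
    ("steroid2", 133, 153, 87),
    ("window", 81, 92, 88),
    ("twocodes", 83, 91, 91),
    ("twocodes_steroid1", 82, 90, 91),
    ("twocodes_steroid2", 133, 153, 87),
    ("no_exclusion", 138, 161, 86),
    ("atopy", 52, 56, 93),
    ("derm_consult", 18, 19, 95),
]


class TestPPV:
    def test_validation_study_point_estimate(self):
        est = ppv(163, 189)
        assert est.percent == 86
        assert est.ppv == pytest.approx(163 / 189)
        assert 0 <= est.ci_low <= est.ppv <= est.ci_high <= 1

    def test_zero_successes(self):
        est = ppv(0, 10)
        assert est.percent == 0
        assert est.ci_low == 0.0

    def test_all_successes(self):
        assert ppv(10, 10).ci_high == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            ppv(0, 0)

    @pytest.mark.parametrize("k,n", [(9, 10), (163, 189), (1, 50), (50, 50), (0, 7)])
    def test_clopper_pearson_matches_binomial_tail_inversion(self, k, n):
        """CP endpoints equal the numeric inversion of exact binomial tails."""
        est = ppv(k, n)

        def upper_tail(p):  # P(X >= k)
            return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))

        def lower_tail(p):  # P(X <= k)
            return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))

        low = 0.0 if k == 0 else brentq(lambda p: upper_tail(p) - 0.025, 1e-12, 1 - 1e-12, xtol=1e-13)
        high = 1.0 if k == n else brentq(lambda p: lower_tail(p) - 0.025, 1e-12, 1 - 1e-12, xtol=1e-13)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    def test_wilson_and_wald_available(self):
        for method in ("wilson", "wald"):
            est = ppv(163, 189, ci_method=method)
            assert est.ci_low <= est.ppv <= est.ci_high
        with pytest.raises(LookupError):
            ppv(1, 2, ci_method="bayes")

    def test_clopper_pearson_coverage_in_simulation(self):
        """Exact interval keeps >= 95% coverage at study-like parameters."""
        rng = np.random.default_rng(5)
        n = 189
        for p in (0.5, 0.86, 0.95):
            draws = rng.binomial(n, p, size=2000)
            covered = 0
            for k in np.unique(draws):
                est = ppv(int(k), n)
                if est.ci_low <= p <= est.ci_high:
                    covered += (draws == k).sum()
            assert covered / draws.size >= 0.95


class TestDetectionFraction:
    @pytest.mark.parametrize(
        "tp,expected", [(83, 51), (18, 11), (163, 100), (157, 96), (52, 32)]
    )
    def test_confirmed_case_fractions(self, tp, expected):
        assert as_percent(detection_fraction(tp, 163)) == expected

    def test_bounds_and_errors(self):
        assert detection_fraction(163, 163) == 1.0
        with pytest.raises(ValueError):
            detection_fraction(1, 0)
        with pytest.raises(ValueError):
            detection_fraction(5, 3)


def fisher_two_sided_oracle(a, b, c, d) -> Fraction:
    """Exact two-sided Fisher p by hypergeometric enumeration (point-mass rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    observed = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= observed)


class TestCompareProportions:
    def test_balanced_table_is_null(self):
        result = compare_proportions(10, 20, 10, 20)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert result.test_used == "pearson_chi2"

    def test_chi_square_matches_hand_formula(self):
        # [[50,50],[90,10]]: chi2 = sum (O-E)^2 / E without continuity correction
        table = np.array([[50, 50], [90, 10]], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        result = compare_proportions(50, 100, 90, 100)
        assert result.test_used == "pearson_chi2"
        assert result.statistic == pytest.approx(by_hand)

    def test_fisher_matches_hypergeometric_enumeration(self):
        result = compare_proportions(8, 10, 2, 10, method="fisher")
        assert result.test_used == "fisher_exact"
        assert result.p_value == pytest.approx(
            float(fisher_two_sided_oracle(8, 2, 2, 8)), rel=1e-10
        )

    def test_auto_switches_to_fisher_on_small_expected_counts(self):
        result = compare_proportions(1, 5, 4, 5)
        assert result.test_used == "fisher_exact"

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            compare_proportions(0, 5, 0, 5)


class TestBlandAltman:
    def test_identical_pairs_zero_difference(self):
        stats = bland_altman([(3.0, 3.0), (7.0, 7.0), (1.0, 1.0)])
        assert stats.mean_diff == 0.0
        assert stats.loa_low == stats.loa_high == 0.0

    def test_closed_form_for_differences_plus_minus_one(self):
        stats = bland_altman([(1.0, 0.0), (-1.0, 0.0)])
        assert stats.mean_diff == 0.0
        assert stats.sd_diff == pytest.approx(math.sqrt(2))
        assert stats.loa_high == pytest.approx(1.96 * math.sqrt(2))
        assert stats.loa_low == pytest.approx(-1.96 * math.sqrt(2))

    def test_planted_lag_recovered_within_ci(self):
        rng = np.random.default_rng(12)
        n = 160
        database = rng.uniform(0, 40, size=n)
        survey = database + rng.normal(0.8, 5.0, size=n)
        stats = bland_altman(np.column_stack([survey, database]))
        assert stats.ci_low <= 0.8 <= stats.ci_high
        assert stats.ci_high - stats.ci_low == pytest.approx(
            2 * 1.96 * stats.sd_diff / math.sqrt(n)
        )

    def test_ci_nested_in_loa(self):
        rng = np.random.default_rng(3)
        pairs = np.column_stack([rng.normal(size=30), rng.normal(size=30)])
        stats = bland_altman(pairs)
        assert stats.loa_low <= stats.ci_low <= stats.ci_high <= stats.loa_high

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])

    def test_plot_written(self, tmp_path):
        path = tmp_path / "ba.png"
        bland_altman([(1.0, 0.5), (2.0, 2.5), (3.0, 2.0)], plot_path=path)
        assert path.stat().st_size > 0


class TestRankSum:
    def test_identical_groups_p_one(self):
        values = list(range(25))
        result = rank_sum(values, values)
        assert result.p_value == pytest.approx(1.0)
        assert result.method == "normal_approx"

    def test_exact_p_for_fully_separated_triples(self):
        # the most extreme of C(6,3)=20 labellings, two-sided: p = 2/20
        result = rank_sum([1, 2, 3], [10, 11, 12])
        assert result.method == "exact"
        assert result.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        a, b = [1.0, 4.0, 6.0, 9.0], [2.0, 3.0, 8.0]
        result = rank_sum(a, b)
        pooled = a + b
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        observed = sum(ranks[v] for v in a)
        mean = len(a) * (len(pooled) + 1) / 2
        count = total = 0
        for combo in itertools.combinations(pooled, len(a)):
            w = sum(ranks[v] for v in combo)
            total += 1
            if abs(w - mean) >= abs(observed - mean) - 1e-12:
                count += 1
        assert result.method == "exact"
        assert result.p_value == pytest.approx(count / total)

    def test_medians_reported(self):
        result = rank_sum([5, 5, 5], [2, 2, 2])
        assert (result.median_a, result.median_b) == (5.0, 2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


def _study_like_outcomes():
    """A labelled sample reconstructed from the printed study counts: 200
    sampled baseline positives, 11 missing labels, 163 confirmed, 26 not."""
    outcomes = []
    strata = itertools.cycle(["child", "adult"])
    for i in range(163):
        outcomes.append(LabelledOutcome(f"Y{i}", True, True, next(strata)))
    for i in range(26):
        outcomes.append(LabelledOutcome(f"N{i}", True, False, next(strata)))
    for i in range(11):
        outcomes.append(LabelledOutcome(f"M{i}", True, None, next(strata)))
    return outcomes


class TestValidateCohort:
    def test_missing_labels_excluded_from_denominator(self):
        outcomes = [
            LabelledOutcome(f"P{i}", True, True, "child") for i in range(8)
        ] + [
            LabelledOutcome("P8", True, False, "adult"),
            LabelledOutcome("P9", True, None, "adult"),
        ]
        report = validate_cohort(outcomes)
        entry = report.variants["baseline"]
        assert entry.positives == 10
        assert entry.labelled_positives == 9
        assert entry.ppv.ppv == pytest.approx(8 / 9)
        assert report.n_missing_labels == 1

    def test_study_counts_reconstructed(self):
        outcomes = _study_like_outcomes()
        confirmed = [o.patient_id for o in outcomes if o.physician_confirmed]
        unconfirmed = [o.patient_id for o in outcomes if o.physician_confirmed is False]
        variants = {}
        for name, tp, n, _ in STUDY_COUNTS:
            if name == "baseline":
                continue
            variants[name] = set(confirmed[:tp]) | set(unconfirmed[: n - tp])
        report = validate_cohort(outcomes, variants)
        for name, tp, n, percent in STUDY_COUNTS:
            entry = report.variants[name]
            assert entry.ppv.true_positives == tp
            assert entry.ppv.positives == n
            assert entry.ppv.percent == percent

    def test_detection_fractions_against_reference_confirmed(self):
        outcomes = _study_like_outcomes()
        confirmed = [o.patient_id for o in outcomes if o.physician_confirmed]
        report = validate_cohort(outcomes, {"twocodes": set(confirmed[:83])})
        assert report.reference_confirmed == 163
        assert as_percent(report.variants["twocodes"].detection) == 51
        assert report.variants["baseline"].detection == 1.0

    def test_empty_variant_gets_notice(self):
        outcomes = _study_like_outcomes()
        report = validate_cohort(outcomes, {"strict": set()})
        entry = report.variants["strict"]
        assert entry.ppv is None
        assert "no positives" in entry.notices

    def test_report_serialises(self, tmp_path):
        report = validate_cohort(_study_like_outcomes())
        text = report.to_json(tmp_path / "report.json")
        assert '"baseline"' in text
        assert "variant" in report.format_table()

    def test_order_invariance_of_ppv(self):
        outcomes = _study_like_outcomes()
        forward = validate_cohort(outcomes).variants["baseline"].ppv
        backward = validate_cohort(list(reversed(outcomes))).variants["baseline"].ppv
        assert forward == backward
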