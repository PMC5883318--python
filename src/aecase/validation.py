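"""Validation statistics for a labelled phenotyping cohort.

Given a sample of algorithm-positive patients whose physicians confirmed or
refuted the diagnosis, this module computes the quantities a code-validation
study reports:

* positive predictive value (PPV) with a two-sided 95% confidence interval
  (Clopper-Pearson exact by default; Wilson and Wald available),
* the detection fraction of a stricter algorithm variant (share of
  physician-confirmed cases the variant still flags),
* chi-square / Fisher comparisons of proportions between groups,
* Bland-Altman agreement between survey-reported and database-derived ages,
* a two-sample Wilcoxon rank-sum comparison (e.g. treatment counts by
  severity group).

Patients with a missing physician label (unreturned survey or blank
response) are excluded from both numerator and denominator of every PPV.
Percent rendering rounds half-up to integer percents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "LabelledOutcome",
    "PPVEstimate",
    "AgreementStats",
    "ProportionTestResult",
    "RankSumResult",
    "VariantValidation",
    "ValidationReport",
    "DegenerateTableError",
    "ppv",
    "detection_fraction",
    "compare_proportions",
    "bland_altman",
    "rank_sum",
    "validate_cohort",
    "as_percent",
]

#: z quantile used for 95% intervals and limits of agreement.
Z_95 = 1.96


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin cannot be tested."""


def as_percent(proportion: float) -> int:
    """Render a proportion as an integer percent, rounding half-up."""
    return int(math.floor(proportion * 100.0 + 0.5))


@dataclass(frozen=True)
class LabelledOutcome:
    """One sampled patient: algorithm decision, physician label, stratum.

    ``physician_confirmed`` is ``None`` when the survey was not returned or
    the response was missing; such patients are excluded from PPV
    denominators.
    """

    patient_id: str
    algorithm_positive: bool
    physician_confirmed: Optional[bool]
    stratum: str = "adult"


@dataclass(frozen=True)
class PPVEstimate:
    """Point estimate and 95% CI for a positive predictive value."""

    true_positives: int
    positives: int
    ppv: float
    ci_low: float
    ci_high: float
    ci_method: str = "clopper_pearson"

    @property
    def percent(self) -> int:
        return as_percent(self.ppv)


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _wilson(k: int, n: int, alpha: float) -> tuple[float, float]:
    z = float(stats.norm.ppf(1 - alpha / 2))
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def _wald(k: int, n: int, alpha: float) -> tuple[float, float]:
    z = float(stats.norm.ppf(1 - alpha / 2))
    p = k / n
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


_CI_METHODS = {
    "clopper_pearson": _clopper_pearson,
    "wilson": _wilson,
    "wald": _wald,
}


def ppv(
    true_positives: int,
    positives: int,
    ci_method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> PPVEstimate:
    """Positive predictive value with a two-sided (1-alpha) CI.

    ``true_positives`` of ``positives`` algorithm-positive patients were
    confirmed by the reference standard.  ``positives`` must be positive.
    """
    if positives <= 0:
        raise ValueError("positives must be > 0")
    if not 0 <= true_positives <= positives:
        raise ValueError("need 0 <= true_positives <= positives")
    try:
        ci_fn = _CI_METHODS[ci_method]
    except KeyError:
        raise LookupError(
            f"unknown ci_method {ci_method!r}; valid: {', '.join(_CI_METHODS)}"
        ) from None
    low, high = ci_fn(true_positives, positives, alpha)
    return PPVEstimate(
        true_positives=true_positives,
        positives=positives,
        ppv=true_positives / positives,
        ci_low=low,
        ci_high=high,
        ci_method=ci_method,
    )


def detection_fraction(variant_tp: int, reference_confirmed: int) -> float:
    """Share of reference-confirmed cases a stricter variant still detects."""
    if reference_confirmed <= 0:
        raise ValueError("reference_confirmed must be > 0")
    if not 0 <= variant_tp <= reference_confirmed:
        raise ValueError("need 0 <= variant_tp <= reference_confirmed")
    return variant_tp / reference_confirmed


class ProportionTestResult(NamedTuple):
    statistic: float
    p_value: float
    test_used: str


def compare_proportions(
    a_success: int,
    a_total: int,
    b_success: int,
    b_total: int,
    method: str = "auto",
) -> ProportionTestResult:
    """Compare two proportions via a 2x2 table.

    ``method="auto"`` uses the Pearson chi-square without continuity
    correction, switching to Fisher's exact test when any expected cell count
    is below 5; ``"pearson"`` or ``"fisher"`` force a test.  For Fisher, the
    reported statistic is the sample odds ratio.  A table with a zero margin
    raises :class:`DegenerateTableError`.
    """
    table = np.array(
        [[a_success, a_total - a_success], [b_success, b_total - b_success]],
        dtype=float,
    )
    if (table < 0).any():
        raise ValueError("successes cannot exceed totals")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    expected = np.outer(rows, cols) / table.sum()
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "pearson"
    if method == "fisher":
        odds_ratio, p_value = stats.fisher_exact(table, alternative="two-sided")
        return ProportionTestResult(float(odds_ratio), float(p_value), "fisher_exact")
    if method == "pearson":
        chi2, p_value, _, _ = stats.chi2_contingency(table, correction=False)
        return ProportionTestResult(float(chi2), float(p_value), "pearson_chi2")
    raise LookupError(f"unknown method {method!r}; valid: auto, pearson, fisher")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired differences (survey minus database)."""

    n: int
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    plot_path: Optional[Union[str, Path]] = None,
) -> AgreementStats:
    """Bland-Altman agreement for paired (survey, database) measurements.

    Differences are survey minus database.  The 95% CI of the mean
    difference uses the normal approximation (mean +/- 1.96 * SD / sqrt(n));
    the limits of agreement are mean +/- 1.96 * SD with SD computed with one
    delta degree of freedom.  If *plot_path* is given, the standard
    mean-vs-difference plot is written there.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (survey, database) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    n = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half_ci = Z_95 * sd / math.sqrt(n)
    stats_out = AgreementStats(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        ci_low=mean - half_ci,
        ci_high=mean + half_ci,
        loa_low=mean - Z_95 * sd,
        loa_high=mean + Z_95 * sd,
    )
    if plot_path is not None:
        _bland_altman_plot(arr, stats_out, Path(plot_path))
    return stats_out


def _bland_altman_plot(arr: np.ndarray, agreement: AgreementStats, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(agreement.mean_diff, color="tab:blue", label="mean difference")
    for y in (agreement.loa_low, agreement.loa_high):
        ax.axhline(y, color="tab:red", linestyle="--", linewidth=1)
    ax.set_xlabel("Mean of survey and database estimates (years)")
    ax.set_ylabel("Survey minus database (years)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class RankSumResult(NamedTuple):
    statistic: float
    p_value: float
    method: str
    median_a: float
    median_b: float


def rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have at most 20
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with midrank tie correction (no continuity correction).
    The statistic is the Mann-Whitney U of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    median_a, median_b = float(np.median(a)), float(np.median(b))
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # every observation tied: no evidence either way
        return RankSumResult(a.size * b.size / 2.0, 1.0, "degenerate", median_a, median_b)
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and max(a.size, b.size) <= 20
    result = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return RankSumResult(
        float(result.statistic),
        min(1.0, float(result.pvalue)),
        "exact" if exact else "normal_approx",
        median_a,
        median_b,
    )


@dataclass
class VariantValidation:
    """Validation summary for one algorithm variant."""

    name: str
    positives: int
    labelled_positives: int
    true_positives: int
    ppv: Optional[PPVEstimate] = None
    ppv_child: Optional[PPVEstimate] = None
    ppv_adult: Optional[PPVEstimate] = None
    detection: Optional[float] = None
    stratum_test: Optional[ProportionTestResult] = None
    notices: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _ppv_dict(est: Optional[PPVEstimate]) -> Optional[dict]:
            if est is None:
                return None
            return {
                "true_positives": est.true_positives,
                "positives": est.positives,
                "ppv": est.ppv,
                "percent": est.percent,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "ci_method": est.ci_method,
            }

        return {
            "name": self.name,
            "positives": self.positives,
            "labelled_positives": self.labelled_positives,
            "true_positives": self.true_positives,
            "ppv": _ppv_dict(self.ppv),
            "ppv_child": _ppv_dict(self.ppv_child),
            "ppv_adult": _ppv_dict(self.ppv_adult),
            "detection": self.detection,
            "detection_percent": None if self.detection is None else as_percent(self.detection),
            "stratum_test": None if self.stratum_test is None else self.stratum_test._asdict(),
            "notices": list(self.notices),
        }


@dataclass
class ValidationReport:
    """Per-variant PPVs, detection fractions and stratified comparisons."""

    reference: str
    n_sampled: int
    n_missing_labels: int
    reference_confirmed: int
    variants: dict[str, VariantValidation] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "n_sampled": self.n_sampled,
            "n_missing_labels": self.n_missing_labels,
            "reference_confirmed": self.reference_confirmed,
            "variants": {name: v.to_dict() for name, v in self.variants.items()},
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def format_table(self) -> str:
        header = (
            f"{'variant':<20} {'TP/pos':>9} {'PPV%':>5} {'95% CI':>9} "
            f"{'child%':>6} {'adult%':>6} {'detect%':>7}"
        )
        lines = [header, "-" * len(header)]
        for name, v in self.variants.items():
            if v.ppv is None:
                lines.append(f"{name:<20} {'-':>9} " + " ".join(v.notices))
                continue
            ci = f"{as_percent(v.ppv.ci_low)}-{as_percent(v.ppv.ci_high)}"
            child = "-" if v.ppv_child is None else str(v.ppv_child.percent)
            adult = "-" if v.ppv_adult is None else str(v.ppv_adult.percent)
            detect = "-" if v.detection is None else str(as_percent(v.detection))
            lines.append(
                f"{name:<20} {v.ppv.true_positives}/{v.ppv.positives:>3}".ljust(31)
                + f"{v.ppv.percent:>4} {ci:>9} {child:>6} {adult:>6} {detect:>7}"
            )
        return "\n".join(lines)


def _ppv_or_none(
    tp: int, n: int, ci_method: str, notices: list[str], label: str
) -> Optional[PPVEstimate]:
    if n == 0:
        notices.append(f"no labelled positives ({label})")
        return None
    return ppv(tp, n, ci_method=ci_method)


def validate_cohort(
    outcomes: Iterable[LabelledOutcome],
    variant_positives: Optional[Mapping[str, Collection[str]]] = None,
    reference: str = "baseline",
    ci_method: str = "clopper_pearson",
) -> ValidationReport:
    """Build a full validation report from labelled outcomes.

    Parameters
    ----------
    outcomes:
        One :class:`LabelledOutcome` per sampled patient, with
        ``algorithm_positive`` referring to the reference (baseline)
        algorithm.
    variant_positives:
        Mapping from variant name to the collection of patient ids that the
        variant flags positive (each expected to be a subset of the sampled
        ids).  The reference algorithm itself is always reported.

    For every variant, PPV (overall and per stratum) is computed over
    labelled positives only; the detection fraction is the share of
    physician-confirmed reference positives that the variant retains.
    """
    outcomes = list(outcomes)
    by_id = {o.patient_id: o for o in outcomes}
    if len(by_id) != len(outcomes):
        raise ValueError("duplicate patient_id in outcomes")
    n_missing = sum(1 for o in outcomes if o.physician_confirmed is None)
    reference_positive_ids = {o.patient_id for o in outcomes if o.algorithm_positive}
    confirmed_ids = {
        o.patient_id
        for o in outcomes
        if o.algorithm_positive and o.physician_confirmed is True
    }

    report = ValidationReport(
        reference=reference,
        n_sampled=len(outcomes),
        n_missing_labels=n_missing,
        reference_confirmed=len(confirmed_ids),
    )

    all_variants: dict[str, Collection[str]] = {reference: reference_positive_ids}
    for name, ids in (variant_positives or {}).items():
        if name != reference:
            all_variants[name] = ids

    for name, ids in all_variants.items():
        positive_ids = set(ids) & set(by_id)
        labelled = [
            by_id[i] for i in positive_ids if by_id[i].physician_confirmed is not None
        ]
        tp_ids = {o.patient_id for o in labelled if o.physician_confirmed}
        entry = VariantValidation(
            name=name,
            positives=len(positive_ids),
            labelled_positives=len(labelled),
            true_positives=len(tp_ids),
        )
        if not positive_ids:
            entry.notices.append("no positives")
            report.variants[name] = entry
            continue
        entry.ppv = _ppv_or_none(
            len(tp_ids), len(labelled), ci_method, entry.notices, "overall"
        )
        strata_counts = {}
        for stratum_name in ("child", "adult"):
            members = [o for o in labelled if o.stratum == stratum_name]
            tp = sum(1 for o in members if o.physician_confirmed)
            strata_counts[stratum_name] = (tp, len(members))
            est = _ppv_or_none(tp, len(members), ci_method, entry.notices, stratum_name)
            if stratum_name == "child":
                entry.ppv_child = est
            else:
                entry.ppv_adult = est
        if report.reference_confirmed > 0:
            entry.detection = detection_fraction(
                len(tp_ids & confirmed_ids), report.reference_confirmed
            )
        else:
            entry.notices.append("no confirmed reference cases")
        (tc, nc), (ta, na) = strata_counts["child"], strata_counts["adult"]
        try:
            entry.stratum_test = compare_proportions(tc, nc, ta, na)
        except (DegenerateTableError, ValueError):
            entry.notices.append("stratified comparison not estimable")
        report.variants[name] = entry
    return report
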