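"""Accuracy-evaluation protocol for dental-age methods.

For each sex and 1-year age group (and the totals) the protocol reports the
mean chronological age (CA), mean dental age (DA), the mean difference
MD = mean(DA - CA) with SD and 95% CI, and the mean absolute difference
MAD = mean(|DA - CA|) with SD. MD > 0 indicates overestimation of age.

The paired DA-vs-CA location test is gated on normality: a one-sample
Kolmogorov-Smirnov test of the differences against a normal distribution
with mean and SD estimated from the sample decides, at the 0.05 level,
between the paired t-test and the Wilcoxon signed-rank test. The Wilcoxon
test drops zero differences, uses mid-ranks for ties, and computes the
exact two-sided p-value for n <= 25 (tie-corrected normal approximation
above). Observer reproducibility of stage assignments is summarised with
unweighted Cohen's kappa over pooled (subject, tooth) ratings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, OutOfRangeError

NORMALITY_ALPHA = 0.05

#: Maximum n for which the exact Wilcoxon null distribution is enumerated.
WILCOXON_EXACT_N = 25


def _round2(value: float) -> float:
    """Round to 2 decimals with decimal half-up semantics (7.005 -> 7.01)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(value))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    ))


@dataclass(frozen=True)
class AgeGroup:
    """Half-open 1-year chronological-age bin (lower, upper]."""

    label: str
    lower: float
    upper: float

    def contains(self, ca: float) -> bool:
        return self.lower < _round2(ca) <= self.upper


#: The nine 1-year bins partitioning (6, 15], labelled "6.01-7.00" ... "14.01-15.00".
AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    AgeGroup(f"{lo}.01-{lo + 1}.00", float(lo), float(lo + 1)) for lo in range(6, 15)
)


def assign_age_group(ca_years: float) -> AgeGroup:
    """The unique bin with lower < CA <= upper, after rounding CA to 2 dp."""
    ca = _round2(ca_years)
    for group in AGE_GROUPS:
        if group.lower < ca <= group.upper:
            return group
    raise OutOfRangeError(f"chronological age {ca_years} outside (6, 15]")


@dataclass(frozen=True)
class AccuracyReport:
    """Agreement summary for one group (or a total) of (CA, DA) pairs."""

    label: str
    n: int
    mean_ca: float
    sd_ca: float
    mean_da: float
    sd_da: float
    md: float
    sd_md: float
    ci_low: float
    ci_high: float
    mad: float
    sd_mad: float
    p_value: float | None = None
    test_used: str | None = None


def accuracy_stats(pairs: Sequence[tuple[float, float]], label: str = "") -> AccuracyReport:
    """MD/MAD summary (without the location test) for (CA, DA) pairs.

    MD = mean(DA - CA); MAD = mean(|DA - CA|); the 95% CI of MD uses the
    t-quantile with n - 1 degrees of freedom. Requires n >= 2 for the SDs.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need at least 2 (CA, DA) pairs")
    ca, da = arr[:, 0], arr[:, 1]
    d = da - ca
    n = len(d)
    sd_md = float(d.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd_md / math.sqrt(n)
    md = float(d.mean())
    return AccuracyReport(
        label=label,
        n=n,
        mean_ca=float(ca.mean()),
        sd_ca=float(ca.std(ddof=1)),
        mean_da=float(da.mean()),
        sd_da=float(da.std(ddof=1)),
        md=md,
        sd_md=sd_md,
        ci_low=md - half,
        ci_high=md + half,
        mad=float(np.abs(d).mean()),
        sd_mad=float(np.abs(d).std(ddof=1)),
    )


def normality_test(differences: Sequence[float]) -> float:
    """One-sample KS p-value of the differences against a fitted normal.

    Mean and SD are estimated from the sample (Lilliefors-style plug-in with
    the standard KS asymptotic p; a documented approximation). A
    zero-variance sample is degenerate: returns p = 0.0 (treated as
    non-normal).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 4:
        raise InsufficientDataError("need at least 4 differences for the KS test")
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(d, "norm", args=(d.mean(), sd)).pvalue)


class LocationTestResult(NamedTuple):
    p_value: float
    test_used: str


def _wilcoxon_exact_sf_table(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null pmf support counts of W+ (doubled) over all 2^n sign patterns."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(differences: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are dropped; tied |differences| receive mid-ranks. For n <= 25
    the exact conditional null distribution of W+ is computed by dynamic
    programming over the (doubled, hence integer) mid-ranks and the
    two-sided p is 2 * min(P(W+ <= w), P(W+ >= w)) capped at 1. Larger n
    uses the tie-corrected normal approximation. All-zero differences give
    p = 1 by convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _wilcoxon_exact_sf_table(doubled)
        total = 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum()) / 48.0
    )
    z = (w_plus - mean) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def paired_location_test(differences: Sequence[float]) -> LocationTestResult:
    """Normality-gated paired test of mean/median difference = 0.

    KS normality p > 0.05 selects the paired t-test; otherwise the Wilcoxon
    signed-rank test. Samples too small for the KS test (n < 4) fall back to
    the t-test. All-zero differences give p = 1 by convention.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("need at least 2 differences")
    if np.all(d == 0):
        return LocationTestResult(1.0, "paired_t")
    try:
        normal = normality_test(d) > NORMALITY_ALPHA
    except InsufficientDataError:
        normal = True
    if normal:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
        return LocationTestResult(p, "paired_t")
    return LocationTestResult(wilcoxon_signed_rank(d), "wilcoxon")


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two equal-length rating sequences.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the product of the two
    raters' marginal category frequencies. Returns NaN when p_e = 1 (both
    raters constant and identical), where kappa is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size == 0:
        raise InsufficientDataError("ratings must be equal-length and non-empty")
    cats, a_idx = np.unique(a, return_inverse=True)
    cats_b, b_idx = np.unique(b, return_inverse=True)
    all_cats = np.unique(np.concatenate([cats, cats_b]))
    k = all_cats.size
    a_idx = np.searchsorted(all_cats, a)
    b_idx = np.searchsorted(all_cats, b)
    table = np.zeros((k, k))
    np.add.at(table, (a_idx, b_idx), 1.0)
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def evaluate_method(
    frame: pd.DataFrame,
    ca_col: str = "ca_years",
    da_col: str = "da_years",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Per-group accuracy reports for a scored cohort.

    *frame* needs one row per subject with chronological age, estimated
    dental age and sex. Returns one report row per sex x age group, one per
    sex total, and a grand total, each with the normality-gated location
    test applied within the group. Empty groups are omitted.
    """
    rows: list[dict] = []

    def _report(sub: pd.DataFrame, sex_label: str, group_label: str) -> None:
        if len(sub) < 2:
            return
        pairs = list(zip(sub[ca_col], sub[da_col]))
        rep = accuracy_stats(pairs, label=group_label)
        test = paired_location_test(np.asarray(sub[da_col]) - np.asarray(sub[ca_col]))
        row = {"sex": sex_label, "age_group": group_label}
        row.update(rep.__dict__)
        row["p_value"] = test.p_value
        row["test_used"] = test.test_used
        del row["label"]
        rows.append(row)

    frame = frame.copy()
    frame["_group"] = [assign_age_group(ca).label for ca in frame[ca_col]]
    for sex in ("male", "female"):
        sub_sex = frame[frame[sex_col] == sex]
        for group in AGE_GROUPS:
            _report(sub_sex[sub_sex["_group"] == group.label], sex, group.label)
        _report(sub_sex, sex, "total")
    _report(frame, "all", "total")
    return pd.DataFrame(rows)
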