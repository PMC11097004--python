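"""Activity budgets, duty-cycled subsampling, and ICC method agreement.

A label stream (one behaviour per sample) becomes a per-individual activity
budget: the percentage of collared time spent in each behaviour, and its
minutes-per-day equivalent.  Two labelling methods (a manual rule tree and a
random-forest model) are compared with the single-rating, absolute-agreement,
two-way mixed-effects intraclass correlation ICC(A,1) of McGraw & Wong, with
its F-based 95% confidence interval, categorised by the Koo & Li bands
(>0.9 excellent, 0.75-0.9 good, 0.5-0.75 moderate, <0.5 poor) applied to the
CI bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import BEHAVIOURS

MIN_PER_DAY_PER_PERCENT = 14.4  # 1% of a day = 14.4 min


@dataclass
class TimeBudget:
    """Share of a deployment spent in each behaviour, one individual."""

    individual_id: str
    percent: dict[str, float]
    total_deployment_s: float
    source: str = "truth"

    @property
    def min_per_day(self) -> dict[str, float]:
        return {b: p * MIN_PER_DAY_PER_PERCENT for b, p in self.percent.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.individual_id, b, self.percent[b], self.min_per_day[b],
              self.source) for b in self.percent],
            columns=["individual_id", "behaviour", "percent", "min_per_day",
                     "source"])


def first_15min_per_hour(t: np.ndarray, window_s: float = 900.0,
                         period_s: float = 3600.0) -> np.ndarray:
    """Boolean mask keeping the first ``window_s`` of every ``period_s``.

    Streams shorter than one hour keep a single (possibly truncated) window.
    """
    t = np.asarray(t, dtype=float)
    return np.mod(t, period_s) < window_s


def time_budget(labels: np.ndarray, frequency: float, deployment_s: float,
                individual_id: str = "cat01", source: str = "truth",
                behaviours=BEHAVIOURS) -> TimeBudget:
    """Summed per-behaviour time as a percent of the labelled stream.

    ``deployment_s`` scales sample counts to seconds of collared time when
    the stream covers the whole deployment; for a subsampled stream the
    percentages are of the labelled time (counts / total counts).
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        raise ValueError("empty label stream")
    percent = {}
    for b in behaviours:
        percent[b] = float((labels == b).sum()) / n * 100.0
    return TimeBudget(individual_id, percent, deployment_s, source)


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class ICCResult:
    """ICC(A,1) estimate with its 95% CI and Koo & Li reliability category."""

    estimate: float
    ci95_low: float
    ci95_high: float
    n_subjects: int
    k_raters: int
    category: str = field(init=False)

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.estimate + 1e-9
                and self.estimate <= self.ci95_high + 1e-9):
            raise ValueError("estimate must lie inside its confidence interval")
        self.category = reliability_category(self.ci95_low, self.ci95_high)


def _band(x: float) -> int:
    if x >= 0.9:
        return 3
    if x >= 0.75:
        return 2
    if x >= 0.5:
        return 1
    return 0


_BAND_NAMES = ("poor", "moderate", "good", "excellent")


def reliability_category(ci_low: float, ci_high: float) -> str:
    """Koo & Li category of a 95% CI; a CI spanning bands gets a compound label."""
    lo, hi = _band(ci_low), _band(ci_high)
    if lo == hi:
        return _BAND_NAMES[lo]
    return f"{_BAND_NAMES[lo]} to {_BAND_NAMES[hi]}"


def anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares (rows=subjects, columns=raters)."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-rating, absolute-agreement, two-way ICC(A,1) with F-based CI.

    ``ratings`` is an n-subjects x k-raters matrix (here: per
    behaviour-individual percentages under two labelling methods).
    Agreement is absolute: a constant offset between raters lowers the
    estimate, unlike a consistency ICC.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be at least 3 subjects x 2 raters")
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom) or np.ptp(x.mean(axis=1)) == 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    r = (msr - mse) / denom

    # F-based CI (McGraw & Wong): Satterthwaite degrees of freedom
    if r >= 1.0 - 1e-12 or mse == 0:
        lo = hi = 1.0
    else:
        a = k * r / (n * (1.0 - r))
        b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    lo = min(lo, r)
    hi = max(hi, r)
    return ICCResult(float(r), float(lo), float(hi), n, k)


def budgets_to_matrix(budgets_a: list[TimeBudget], budgets_b: list[TimeBudget],
                      exclude: frozenset[str] | set[str] = frozenset()
                      ) -> np.ndarray:
    """Pair two methods' budgets into an (individuals x behaviours, 2) matrix."""
    ids_a = [b.individual_id for b in budgets_a]
    ids_b = [b.individual_id for b in budgets_b]
    if ids_a != ids_b:
        raise ValueError("mismatched individuals between the two methods")
    rows = []
    for ba, bb in zip(budgets_a, budgets_b):
        if set(ba.percent) != set(bb.percent):
            raise ValueError("mismatched behaviours between the two methods")
        for beh in ba.percent:
            if beh in exclude:
                continue
            rows.append((ba.percent[beh], bb.percent[beh]))
    return np.array(rows)


def compare_methods(budget_ref: list[TimeBudget], budget_rf: list[TimeBudget],
                    exclude: frozenset[str] | set[str] = frozenset()
                    ) -> ICCResult:
    """ICC(A,1) between two methods over pooled behaviour-individual pairs.

    The rating unit is one behaviour of one individual; ``exclude`` drops
    behaviours (e.g. rest, whose dominance can inflate agreement).  Excluded
    behaviours are simply removed from the pairing — remaining percentages
    are not renormalised.
    """
    return icc_a1(budgets_to_matrix(budget_ref, budget_rf, exclude))
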