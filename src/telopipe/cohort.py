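"""Gestational timepoint assignment and longitudinal cohort statistics.

Blood draws are binned into three gestational windows: Timepoint 1 up to
20^0/7 weeks, Timepoint 2 from 20^1/7 to 36^6/7 weeks, and Timepoint 3
from 37^0/7 weeks through 9 weeks postpartum. Postpartum draws are placed
on a pseudo-gestational-age scale (delivery GA plus postpartum days,
capped at 50 weeks) so all draws share one time axis. Within-person
telomere change between timepoints is tested with the Wilcoxon
signed-rank test, postpartum T/S is compared between delivery modes with
the Wilcoxon rank-sum test, and the delivery-mode effect is re-estimated
as an age-adjusted ordinary least squares model on log T/S. Descriptive
tables follow the convention that percentages exclude missing values,
with half-up rounding to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._exact import (
    RANK_SUM_EXACT_N,
    SIGNED_RANK_EXACT_N,
    rank_sum_exact,
    signed_rank_exact,
)

__all__ = [
    "DrawEvent",
    "PairedComparison",
    "RegressionResult",
    "assign_timepoint",
    "postpartum_to_pseudo_ga",
    "paired_differences",
    "signed_rank_test",
    "rank_sum_test",
    "rank_sum_by_mode",
    "delivery_mode_model",
    "describe_cohort",
    "completeness_range",
    "round_half_up",
    "OutOfWindowError",
    "EmptyPairsError",
]

#: Pseudo-gestational-age cap for postpartum draws, weeks.
PSEUDO_GA_CAP = 50.0
#: Maximum postpartum delay for a Timepoint 3 draw, days (9 weeks).
MAX_POSTPARTUM_DAYS = 63


class OutOfWindowError(ValueError):
    """A draw falls outside every study window (postpartum > 9 weeks)."""


class EmptyPairsError(ValueError):
    """No subject has measurements at both requested timepoints."""


@dataclass(frozen=True)
class DrawEvent:
    subject_id: str
    ga_weeks: int
    ga_days: int
    postpartum_days: int | None
    pseudo_ga: float
    timepoint: int


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple[int, int]
    n_pairs: int
    mean_diff: float
    sd_diff: float
    statistic: float
    p_value: float
    exact: bool


@dataclass(frozen=True)
class RegressionResult:
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float


def assign_timepoint(
    ga_weeks: int, ga_days: int = 0, postpartum_days: int | None = None
) -> int:
    """Assign a draw to Timepoint 1, 2 or 3 by its gestational window.

    A draw at exactly 20^0/7 weeks goes to Timepoint 1 (the window
    definitions otherwise leave that boundary day unassigned; a warning
    records the decision). Postpartum draws within 9 weeks are
    Timepoint 3; later postpartum draws raise :class:`OutOfWindowError`.
    """
    if not 0 <= ga_days <= 6:
        raise ValueError("ga_days must be in [0, 6]")
    if ga_weeks < 0:
        raise ValueError("ga_weeks must be non-negative")
    if postpartum_days is not None:
        if postpartum_days < 0:
            raise ValueError("postpartum_days must be non-negative")
        if postpartum_days > MAX_POSTPARTUM_DAYS:
            raise OutOfWindowError(
                f"draw {postpartum_days} days postpartum is beyond the 9-week window"
            )
        return 3
    total_days = ga_weeks * 7 + ga_days
    if total_days <= 20 * 7:
        if total_days == 20 * 7:
            warnings.warn(
                "draw at exactly 20^0/7 weeks assigned to Timepoint 1 "
                "(boundary policy)",
                UserWarning,
                stacklevel=2,
            )
        return 1
    if total_days <= 36 * 7 + 6:
        return 2
    return 3


def postpartum_to_pseudo_ga(
    ga_delivery_weeks: int, ga_delivery_days: int, postpartum_days: int
) -> float:
    """Postpartum draw time on the common gestational scale, capped at 50 weeks."""
    if not 0 <= ga_delivery_days <= 6:
        raise ValueError("ga_delivery_days must be in [0, 6]")
    if postpartum_days > MAX_POSTPARTUM_DAYS:
        raise OutOfWindowError("postpartum draw beyond the 9-week window")
    pseudo = ga_delivery_weeks + ga_delivery_days / 7.0 + postpartum_days / 7.0
    return float(min(pseudo, PSEUDO_GA_CAP))


def signed_rank_test(
    diffs: Sequence[float], exact_threshold: int = SIGNED_RANK_EXACT_N
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original convention). The
    null distribution is enumerated exactly when the informative sample
    size is at most ``exact_threshold``; otherwise a normal approximation
    with mid-rank tie correction is used. Returns (W+, p, exact_flag).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("no informative pairs (all differences zero)", UserWarning, stacklevel=2)
        return 0.0, 1.0, True
    if n <= exact_threshold:
        w_plus, p = signed_rank_exact(d)
        return w_plus, p, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z))), False


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = RANK_SUM_EXACT_N
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum test; exact for small tie-free samples.

    Returns (W, p, exact_flag) with W the rank sum of ``x``. The exact
    branch enumerates the label-shuffle null when the pooled sample size
    is at most ``exact_max_n`` and tie-free; otherwise the tie-corrected
    normal approximation (without continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if pooled.size <= exact_max_n and tie_free:
        w, p = rank_sum_exact(x, y)
        return w, p, True
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    w = float(stats.rankdata(pooled)[: x.size].sum())
    return w, float(res.pvalue), False


def paired_differences(ltl_table: pd.DataFrame, pair: tuple[int, int]) -> PairedComparison:
    """Within-person T/S change between two timepoints.

    ``ltl_table`` needs columns ``subject_id``, ``timepoint``, ``ts``.
    The difference is later minus earlier; subjects lacking either
    timepoint are excluded.
    """
    earlier, later = sorted(pair)
    wide = ltl_table.pivot_table(index="subject_id", columns="timepoint", values="ts")
    if earlier not in wide.columns or later not in wide.columns:
        raise EmptyPairsError(f"no subjects with both timepoints {earlier} and {later}")
    both = wide[[earlier, later]].dropna()
    if both.empty:
        raise EmptyPairsError(f"no subjects with both timepoints {earlier} and {later}")
    diffs = (both[later] - both[earlier]).to_numpy()
    w, p, exact = signed_rank_test(diffs)
    return PairedComparison(
        pair=(earlier, later),
        n_pairs=int(diffs.size),
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        statistic=w,
        p_value=p,
        exact=exact,
    )


def rank_sum_by_mode(
    postpartum_ltl: Sequence[float], delivery_mode: Sequence[str]
) -> tuple[float, float, dict[str, int]]:
    """Compare postpartum T/S between vaginal and cesarean deliveries.

    ``delivery_mode`` entries are "cesarean" or "vaginal" (any two
    labels work; groups are ordered alphabetically and W is the rank sum
    of the first). Returns (W, two-sided p, group sizes).
    """
    ltl = np.asarray(postpartum_ltl, dtype=float)
    mode = np.asarray(delivery_mode)
    levels = sorted(set(mode.tolist()))
    if len(levels) != 2:
        raise ValueError(f"delivery_mode must have exactly 2 levels, got {levels}")
    x = ltl[mode == levels[0]]
    y = ltl[mode == levels[1]]
    w, p, _ = rank_sum_test(x, y)
    return w, p, {levels[0]: int(x.size), levels[1]: int(y.size)}


def delivery_mode_model(
    postpartum_ltl: Sequence[float],
    age: Sequence[float],
    mode: Sequence[int],
) -> RegressionResult:
    """Age-adjusted delivery-mode effect on log postpartum T/S.

    OLS of log(T/S) on a cesarean indicator (1 = cesarean) and maternal
    age; returns the cesarean coefficient on the log scale with its 95%
    confidence interval.
    """
    ltl = np.asarray(postpartum_ltl, dtype=float)
    if np.any(ltl <= 0):
        raise ValueError("T/S ratios must be positive for log transformation")
    mode = np.asarray(mode, dtype=float)
    counts = [int((mode == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 3 or counts[0] + counts[1] != mode.size:
        raise ValueError("need >=3 observations per delivery-mode group (coded 0/1)")
    exog = sm.add_constant(
        pd.DataFrame({"cesarean": mode, "age": np.asarray(age, dtype=float)})
    )
    fit = sm.OLS(np.log(ltl), exog).fit()
    ci = fit.conf_int().loc["cesarean"]
    return RegressionResult(
        coefficient=float(fit.params["cesarean"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["cesarean"]),
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, matching how printed tables round."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def describe_cohort(
    table: pd.DataFrame, variables: Mapping[str, str]
) -> pd.DataFrame:
    """Descriptive table: n (%) for categorical, mean +- SD for continuous.

    ``variables`` maps column name to "categorical" or "continuous".
    Percentages use per-variable denominators that exclude missing
    values and are half-up rounded to one decimal.
    """
    rows = []
    for name, kind in variables.items():
        col = table[name]
        if kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce").dropna()
            rows.append(
                {
                    "variable": name,
                    "level": "",
                    "n": int(vals.size),
                    "value": f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}",
                    "percent": np.nan,
                }
            )
        elif kind == "categorical":
            observed = col.dropna()
            denom = int(observed.size)
            for level, count in observed.value_counts().sort_index().items():
                pct = round_half_up(100.0 * count / denom) if denom else 0.0
                rows.append(
                    {
                        "variable": name,
                        "level": str(level),
                        "n": int(count),
                        "value": f"{int(count)} ({pct}%)",
                        "percent": pct,
                    }
                )
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {name!r}")
    return pd.DataFrame(rows, columns=["variable", "level", "n", "value", "percent"])


def categorical_percent(count: int, total: int, missing: int = 0) -> float:
    """n/(total - missing) as a percent, half-up rounded to one decimal."""
    denom = total - missing
    if denom <= 0:
        raise ValueError("denominator after excluding missing must be positive")
    return round_half_up(100.0 * count / denom)


def completeness_range(
    survey: pd.DataFrame | Sequence[int], eligible: int | Sequence[int]
) -> tuple[float, float]:
    """(min, max) per-item completeness percent across survey items.

    ``survey`` is either a subjects x items table (completeness counted
    from non-missing cells) or a sequence of per-item respondent counts;
    ``eligible`` is the per-item (or common) eligible denominator.
    """
    if isinstance(survey, pd.DataFrame):
        counts = survey.notna().sum().to_numpy(dtype=float)
    else:
        counts = np.asarray(list(survey), dtype=float)
    denom = np.asarray(eligible, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("eligible denominators must be positive")
    pct = 100.0 * counts / denom
    return round_half_up(float(pct.min())), round_half_up(float(pct.max()))
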