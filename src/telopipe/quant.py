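"""qPCR standard-curve quantification and triplicate quality control.

Converts raw quantification cycles (Cq) into per-sample relative T/S
ratios: a linear standard curve (Cq versus log10 input quantity in ng) is
fit per run and per target from a reference-DNA dilution series, unknown
wells are interpolated back onto the ng scale, triplicate wells are
screened with Dixon's Q test, and the arithmetic means of the retained T
(telomere) and S (single-copy gene) quantities form the raw T/S ratio.

The Q-test removal decision is made on the Cq scale while retained wells
are averaged on the quantity (concentration) scale; both choices are
stated explicitly because the ratio is sensitive to each (see
``quantify_sample``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "TriplicateQC",
    "SampleQuantification",
    "fit_standard_curve",
    "interpolate_quantity",
    "dixon_q_test",
    "quantify_sample",
    "FitError",
    "InvalidAssayError",
    "QuantificationError",
    "AssayWarning",
]


class FitError(ValueError):
    """Standard curve cannot be fit (e.g. fewer than 2 distinct quantities)."""


class InvalidAssayError(ValueError):
    """The fitted curve is not a valid amplification assay (slope >= 0)."""


class QuantificationError(ValueError):
    """A sample cannot be quantified (e.g. no usable wells for a target)."""


class AssayWarning(UserWarning):
    """Assay-quality warning (efficiency out of range, extrapolation...)."""


# Two-tailed Dixon r10 critical values for n = 3 (Rorabacher 1991).
DIXON_Q_CRITICAL_3 = {0.01: 0.994, 0.05: 0.970, 0.10: 0.941}

#: Acceptable PCR efficiency window, percent.
EFFICIENCY_RANGE = (80.0, 110.0)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq on log10(quantity) for one target in one run.

    ``efficiency`` is the per-cycle amplification gain implied by the
    slope, ``(10**(-1/slope) - 1) * 100`` percent; perfect doubling
    chemistry gives slope -3.3219 and efficiency 100%.
    """

    target: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    q_min: float = 0.108
    q_max: float = 26.0


@dataclass(frozen=True)
class TriplicateQC:
    """Dixon's Q screening record for one triplicate of quantities (ng)."""

    values: tuple[float, float, float]
    q_statistic: float | None
    removed_index: int | None
    kept_mean: float


@dataclass(frozen=True)
class SampleQuantification:
    sample_id: str
    t_quantity: float
    s_quantity: float
    raw_ts: float
    qc: tuple[TriplicateQC, TriplicateQC] = field(repr=False, default=None)


def fit_standard_curve(
    standard_wells: Sequence[tuple[float, float]], target: str = ""
) -> StandardCurve:
    """Fit the standard curve Cq = intercept + slope * log10(quantity).

    Parameters
    ----------
    standard_wells : sequence of (quantity_ng, cq)
        Dilution-series wells; quantities must be positive with at least
        two distinct values.
    target : str
        Assay target label ("T" or "S"), carried through for reporting.

    Raises
    ------
    FitError
        Fewer than two distinct quantities, or non-positive quantity.
    InvalidAssayError
        Fitted slope >= 0 (no amplification signal).
    """
    wells = list(standard_wells)
    q = np.asarray([w[0] for w in wells], dtype=float)
    cq = np.asarray([w[1] for w in wells], dtype=float)
    if q.size and np.any(q <= 0):
        raise FitError("standard quantities must be strictly positive")
    if np.unique(q).size < 2:
        raise FitError("standard curve requires at least 2 distinct quantities")
    res = stats.linregress(np.log10(q), cq)
    if res.slope >= 0:
        raise InvalidAssayError(f"non-negative standard-curve slope {res.slope:.4g}")
    efficiency = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    if not EFFICIENCY_RANGE[0] <= efficiency <= EFFICIENCY_RANGE[1]:
        warnings.warn(
            f"{target or 'assay'}: PCR efficiency {efficiency:.1f}% outside "
            f"[{EFFICIENCY_RANGE[0]:.0f}%, {EFFICIENCY_RANGE[1]:.0f}%]",
            AssayWarning,
            stacklevel=2,
        )
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
        q_min=float(q.min()),
        q_max=float(q.max()),
    )


def interpolate_quantity(cq: float, curve: StandardCurve, warn: bool = True) -> float:
    """Invert the standard curve: quantity = 10**((cq - intercept)/slope).

    Emits :class:`AssayWarning` when the result lies outside the fitted
    standard range (extrapolation).
    """
    quantity = 10.0 ** ((cq - curve.intercept) / curve.slope)
    if warn and not curve.q_min <= quantity <= curve.q_max:
        warnings.warn(
            f"interpolated quantity {quantity:.3g} ng outside standard range "
            f"[{curve.q_min:.3g}, {curve.q_max:.3g}] ng",
            AssayWarning,
            stacklevel=2,
        )
    return quantity


def dixon_q_test(values: Sequence[float], alpha: float = 0.05) -> TriplicateQC:
    """Dixon's Q outlier test for a triplicate of quantities.

    Q = |suspect - nearest neighbour| / range, where the suspect is the
    extremum farther from the median; the suspect is removed iff Q exceeds
    the two-tailed critical value for n = 3 (0.970 at alpha = 0.05). A
    zero-range triplicate is kept untouched. At most one value is ever
    removed.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (3,):
        raise ValueError("dixon_q_test requires exactly 3 values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("dixon_q_test requires finite values")
    try:
        crit = DIXON_Q_CRITICAL_3[alpha]
    except KeyError:
        raise ValueError(
            f"no n=3 critical value tabulated for alpha={alpha}; "
            f"choose from {sorted(DIXON_Q_CRITICAL_3)}"
        ) from None
    order = np.argsort(vals, kind="stable")
    lo, mid, hi = vals[order]
    value_range = hi - lo
    if value_range == 0:
        return TriplicateQC(tuple(vals), None, None, float(vals.mean()))
    gap_hi = hi - mid
    gap_lo = mid - lo
    if gap_hi >= gap_lo:
        q_stat = gap_hi / value_range
        suspect = int(order[2])
    else:
        q_stat = gap_lo / value_range
        suspect = int(order[0])
    if q_stat > crit:
        kept = np.delete(vals, suspect)
        return TriplicateQC(tuple(vals), float(q_stat), suspect, float(kept.mean()))
    return TriplicateQC(tuple(vals), float(q_stat), None, float(vals.mean()))


def _target_quantity(
    cqs: Sequence[float], curve: StandardCurve, alpha: float, label: str
) -> tuple[float, TriplicateQC | None]:
    cqs = np.asarray(cqs, dtype=float)
    cqs = cqs[np.isfinite(cqs)]
    if cqs.size == 0:
        raise QuantificationError(f"no usable {label} wells")
    quantities = np.array([interpolate_quantity(c, curve, warn=False) for c in cqs])
    if quantities.size == 3:
        # The removal decision runs on the Cq scale: a failed well (high
        # Cq) maps to a near-zero concentration where the Q gap ratio
        # saturates at mid/high and can stay under the critical value, so
        # gross dropouts would slip through a concentration-scale test.
        # Cq is log-concentration, so the decision is shift-invariant and
        # catches displacements in either direction.
        cq_qc = dixon_q_test(cqs, alpha=alpha)
        kept = (
            np.delete(quantities, cq_qc.removed_index)
            if cq_qc.removed_index is not None
            else quantities
        )
        qc = TriplicateQC(
            tuple(quantities),
            cq_qc.q_statistic,
            cq_qc.removed_index,
            float(kept.mean()),
        )
        return qc.kept_mean, qc
    return float(quantities.mean()), None


def quantify_sample(
    sample_id: str,
    t_cqs: Sequence[float],
    s_cqs: Sequence[float],
    curve_t: StandardCurve,
    curve_s: StandardCurve,
    alpha: float = 0.05,
) -> SampleQuantification:
    """Quantify one sample from its T and S triplicate Cq values.

    Dixon's Q removal decision is made per target on the Cq scale (see
    note in ``_target_quantity``); the retained wells' interpolated
    quantities are averaged arithmetically, and raw T/S is the ratio of
    the retained means.
    """
    t_mean, t_qc = _target_quantity(t_cqs, curve_t, alpha, "T")
    s_mean, s_qc = _target_quantity(s_cqs, curve_s, alpha, "S")
    if s_mean <= 0 or t_mean <= 0:
        raise QuantificationError(f"non-positive mean quantity for {sample_id}")
    return SampleQuantification(
        sample_id=sample_id,
        t_quantity=t_mean,
        s_quantity=s_mean,
        raw_ts=t_mean / s_mean,
        qc=(t_qc, s_qc),
    )
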