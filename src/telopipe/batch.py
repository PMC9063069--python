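"""Replicate concordance, third-run resolution, and control-DNA batch adjustment.

Each sample's T/S ratio is measured in two independent runs; when the two
values disagree by more than 7% (relative to their mean) the sample is
measured a third time and the two closest values are reported. Run-to-run
drift is corrected with a panel of 8 control DNAs carried on every run:
each control's observed T/S is compared against its mean over the first
reference runs, the per-control ratios reference/observed are averaged
into a single run factor, and every raw ratio on the run is multiplied by
that factor. The orientation (reference over observed) means a run that
reads high is scaled down, so a planted multiplicative run drift cancels
exactly in the noiseless limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReplicateSet",
    "BatchAdjustment",
    "AssayQC",
    "concordance_check",
    "resolve_replicates",
    "build_reference",
    "adjust_run",
    "assay_cv",
    "NeedsThirdRunError",
    "ReferenceError",
]

#: Default duplicate concordance threshold (7% of the replicate mean).
CONCORDANCE_THRESHOLD = 0.07
#: Number of early runs averaged into the control reference panel.
REFERENCE_RUN_COUNT = 10


class NeedsThirdRunError(Exception):
    """Two replicate T/S values are discordant; a third run is required."""


class ReferenceError(ValueError):
    """A control DNA is missing from a run used to build the reference."""


@dataclass(frozen=True)
class ReplicateSet:
    sample_id: str
    measurements: tuple[float, ...]
    reported_ts: float
    concordant: bool
    runs_used: tuple[str, ...]


@dataclass(frozen=True)
class BatchAdjustment:
    """Per-run multiplicative correction derived from the control panel."""

    run_id: str
    control_factors: dict[str, float]
    run_factor: float
    reference_means: dict[str, float]


@dataclass(frozen=True)
class AssayQC:
    cv_percent: float
    per_control: dict[str, tuple[float, float]]  # control -> (sd, mean)


def concordance_check(a: float, b: float, threshold: float = CONCORDANCE_THRESHOLD) -> bool:
    """True iff |a - b| / mean(a, b) <= threshold."""
    if a <= 0 or b <= 0:
        raise ValueError("T/S ratios must be positive")
    return abs(a - b) / ((a + b) / 2.0) <= threshold


def resolve_replicates(
    measurements: Sequence[float],
    run_ids: Sequence[str] | None = None,
    threshold: float = CONCORDANCE_THRESHOLD,
) -> ReplicateSet:
    """Resolve 2-3 replicate T/S measurements into one reported value.

    Two concordant values report their mean. Two discordant values raise
    :class:`NeedsThirdRunError`. With three values the pair with the
    smallest absolute difference is reported (mean of the pair); distance
    ties break toward the pair containing the earliest run.
    """
    vals = [float(v) for v in measurements]
    if not all(v > 0 for v in vals):
        raise ValueError("T/S ratios must be positive")
    if run_ids is None:
        run_ids = [f"r{i + 1}" for i in range(len(vals))]
    run_ids = [str(r) for r in run_ids]
    if len(run_ids) != len(vals):
        raise ValueError("run_ids must match measurements")
    sample_id = ""
    if len(vals) == 2:
        if not concordance_check(vals[0], vals[1], threshold):
            raise NeedsThirdRunError(
                f"replicates {vals[0]:.4g} and {vals[1]:.4g} differ by more "
                f"than {threshold:.0%}; run the sample a third time"
            )
        return ReplicateSet(sample_id, tuple(vals), float(np.mean(vals)), True, tuple(run_ids))
    if len(vals) == 3:
        # earliest-run tie-break: measurements arrive in run order, so on a
        # distance tie prefer the pair whose first member ran earliest
        pairs = sorted(
            combinations(range(3), 2),
            key=lambda ij: (abs(vals[ij[0]] - vals[ij[1]]), ij[0], ij[1]),
        )
        i, j = pairs[0]
        reported = (vals[i] + vals[j]) / 2.0
        return ReplicateSet(
            sample_id, tuple(vals), float(reported), False, (run_ids[i], run_ids[j])
        )
    raise ValueError("resolve_replicates requires 2 or 3 measurements")


def build_reference(
    first_runs: Sequence[Mapping[str, float]],
    expected_runs: int = REFERENCE_RUN_COUNT,
) -> dict[str, float]:
    """Per-control mean T/S across the supplied early runs.

    Every run must contain every control present in the first run; fewer
    than ``expected_runs`` runs is allowed with a warning.
    """
    if not first_runs:
        raise ReferenceError("at least one run of controls is required")
    controls = list(first_runs[0].keys())
    for idx, run in enumerate(first_runs):
        missing = [c for c in controls if c not in run]
        if missing or len(run) != len(controls):
            raise ReferenceError(f"run {idx} control panel mismatch: missing {missing}")
    if len(first_runs) < expected_runs:
        warnings.warn(
            f"reference built from {len(first_runs)} runs (expected {expected_runs})",
            UserWarning,
            stacklevel=2,
        )
    return {c: float(np.mean([run[c] for run in first_runs])) for c in controls}


def make_adjustment(
    run_id: str,
    observed_controls: Mapping[str, float],
    reference_means: Mapping[str, float],
) -> BatchAdjustment:
    """Build the run's adjustment from its observed control T/S values."""
    factors = {}
    for control, ref in reference_means.items():
        if control not in observed_controls:
            raise ReferenceError(f"control {control!r} missing from run {run_id}")
        obs = observed_controls[control]
        if obs <= 0 or ref <= 0:
            raise ValueError("control T/S ratios must be positive")
        factors[control] = ref / obs
    run_factor = float(np.mean(list(factors.values())))
    return BatchAdjustment(run_id, factors, run_factor, dict(reference_means))


def adjust_run(
    raw_ts_values: Sequence[float] | Mapping[str, float],
    adjustment: BatchAdjustment,
):
    """Multiply each raw T/S on the run by the run factor."""
    if isinstance(raw_ts_values, Mapping):
        return {k: v * adjustment.run_factor for k, v in raw_ts_values.items()}
    return [v * adjustment.run_factor for v in raw_ts_values]


def assay_cv(control_history: Mapping[str, Sequence[float]]) -> AssayQC:
    """Assay precision from repeated (adjusted) control measurements.

    Per-control CV = SD/mean (sample SD); ``cv_percent`` is the mean CV
    across controls with at least two measurements, in percent.
    """
    per_control: dict[str, tuple[float, float]] = {}
    cvs = []
    for control, values in control_history.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size < 2:
            continue
        sd = float(vals.std(ddof=1))
        mean = float(vals.mean())
        per_control[control] = (sd, mean)
        cvs.append(sd / mean)
    if not cvs:
        raise ValueError("assay_cv requires >=2 measurements for >=1 control")
    return AssayQC(cv_percent=float(np.mean(cvs) * 100.0), per_control=per_control)
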