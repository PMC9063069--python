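"""Synthetic qPCR plates, pregnancy cohort, and stress survey with known truth.

Emulates the full measurement chain of a longitudinal leukocyte telomere
length (LTL) study so the downstream pipeline can be tested end to end
without any real data: a reference-DNA dilution series on every run,
triplicate wells with Gaussian Cq noise, occasional gross outlier wells,
per-run multiplicative batch drift, a panel of 8 control DNAs carried on
every run, a cohort with up to three blood draws per subject inside the
three gestational windows, a planted cesarean effect on postpartum T/S,
and a 79-feature mixed-type stress survey whose designated sleep-quality
feature has a planted association with true T/S. Every random quantity
flows from ``SimConfig.seed`` through named ``SeedSequence`` streams, so
identical configurations produce byte-identical outputs, and every
emitted well/sample/subject is mirrored in a :class:`GroundTruth` record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PSEUDO_GA_CAP, assign_timepoint
from .screen import StressFeatureTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "STANDARD_SERIES_NG",
    "CONTROL_IDS",
    "slope_for_efficiency",
    "simulate_dilution_series",
    "simulate_plate_run",
    "simulate_plates",
    "simulate_cohort",
    "simulate_stress_survey",
]

#: Reference-DNA dilution series included in every run (ng).
STANDARD_SERIES_NG = (26.0, 8.75, 2.9, 0.97, 0.324, 0.108)
#: The 8 named control DNAs carried on every run.
CONTROL_IDS = tuple(f"ctrl{i:02d}" for i in range(1, 9))
#: Genomic DNA input per reaction (ng).
INPUT_DNA_NG = 6.6
#: True Cq at 1 ng input, per target.
TRUE_INTERCEPT = {"T": 22.0, "S": 27.0}

# draw-presence probabilities per timepoint and postpartum fraction of
# Timepoint 3 draws, matching the cohort structure the generator emulates
_PRESENCE = (41 / 46, 39 / 46, 35 / 46)
_POSTPARTUM_FRAC = 32 / 35

_RACE_LEVELS = ("Asian", "Hispanic", "Indian", "Multi-race", "White")
_RACE_PROBS = (7 / 45, 6 / 45, 3 / 45, 3 / 45, 26 / 45)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Efficiencies are fractions (0.932 means 93.2% per-cycle gain); the
    baseline T/S distribution, within-pregnancy drift, cesarean log
    effect and cesarean rate are the population the generator emulates.
    ``batch_drift_sds`` is the log-scale SD of the per-run, per-target
    quantity multiplier; ``sleep_effect`` is the log-T/S shift per unit
    (SD) of the latent sleep-quality score.
    """

    n_subjects: int = 46
    true_efficiency_T: float = 0.932
    true_efficiency_S: float = 0.940
    cq_noise_sd: float = 0.04
    outlier_rate: float = 0.01
    batch_drift_sds: float = 0.04
    baseline_ts_mean: float = 1.15
    baseline_ts_sd: float = 0.26
    visit_noise_sd: float = 0.18
    within_person_drift: float = -0.07
    cesarean_log_effect: float = -0.18
    cesarean_rate: float = 0.391
    sleep_effect: float = 0.08
    n_features: int = 79
    missing_rate: float = 0.05
    samples_per_run: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "cesarean_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("cq_noise_sd", "batch_drift_sds", "baseline_ts_sd", "visit_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("true_efficiency_T", "true_efficiency_S"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.2:
                raise ValueError(f"{name} must be in (0, 1.2], got {v}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.samples_per_run < 1:
            raise ValueError("samples_per_run must be >= 1")

    @property
    def between_person_sd(self) -> float:
        """Between-person component of the cross-sectional T/S SD.

        ``baseline_ts_sd`` is the total cross-sectional SD; the visit
        component is carved out so a single timepoint still scatters
        with SD ``baseline_ts_sd`` while within-person differences
        scatter with SD ``sqrt(2) * visit_noise_sd``.
        """
        return math.sqrt(max(self.baseline_ts_sd**2 - self.visit_noise_sd**2, 1e-12))

    @property
    def baseline_log_sd(self) -> float:
        """Log-scale SD of the between-person baseline distribution."""
        return self.between_person_sd / self.baseline_ts_mean

    @property
    def outcome_log_sd(self) -> float:
        """Approximate log-scale SD of a single measured T/S outcome."""
        return self.baseline_ts_sd / self.baseline_ts_mean


@dataclass
class GroundTruth:
    """Planted truth keyed exactly like the emitted tables."""

    true_ts: dict[str, float] = field(default_factory=dict)  # sample_id -> T/S
    sleep_score: dict[str, float] = field(default_factory=dict)  # subject -> z
    control_ts: dict[str, float] = field(default_factory=dict)  # control -> T/S
    run_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    outlier_wells: list[tuple[str, str, str]] = field(default_factory=list)
    feature_effects: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        self.true_ts.update(other.true_ts)
        self.sleep_score.update(other.sleep_score)
        self.control_ts.update(other.control_ts)
        self.run_multipliers.update(other.run_multipliers)
        self.outlier_wells.extend(other.outlier_wells)
        self.feature_effects.update(other.feature_effects)
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_wells"] = [list(w) for w in self.outlier_wells]
        return d


def slope_for_efficiency(efficiency: float) -> float:
    """Standard-curve slope (cycles per log10 ng) for a given efficiency."""
    return -1.0 / math.log10(1.0 + efficiency)


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *stream]))


def simulate_dilution_series(
    slope: float,
    intercept: float,
    quantities: Sequence[float] = STANDARD_SERIES_NG,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Standard wells (quantity_ng, Cq) along a dilution series.

    Cq = intercept + slope * log10(quantity) + Normal(0, noise_sd).
    """
    q = np.asarray(list(quantities), dtype=float)
    if np.any(q <= 0):
        raise ValueError("dilution quantities must be strictly positive")
    if len(set(q.tolist())) < 2:
        raise ValueError("at least 2 distinct quantities are required")
    if rng is None:
        rng = np.random.default_rng(seed)
    cq = intercept + slope * np.log10(q) + rng.normal(0.0, noise_sd, size=q.size)
    return list(zip(q.tolist(), cq.tolist()))


def control_true_ts(config: SimConfig) -> dict[str, float]:
    """Fixed true T/S of the 8 control DNAs (deterministic per seed)."""
    rng = _rng(config, 77)
    sd = config.baseline_log_sd
    log_ts = rng.normal(math.log(config.baseline_ts_mean) - sd**2 / 2.0, sd, len(CONTROL_IDS))
    return {c: float(np.exp(v)) for c, v in zip(CONTROL_IDS, log_ts)}


def _well_name(index: int) -> str:
    row, col = divmod(index, 24)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_plate_run(
    config: SimConfig,
    run_index: int,
    samples: pd.DataFrame,
    control_ts: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """One qPCR run: paired T- and S-target plates plus its truth slice.

    ``samples`` needs columns ``sample_id`` and ``true_ts``. Each run
    carries the dilution series (triplicate per concentration), the 8
    control DNAs and every manifest sample in 3 wells per target. A
    per-run, per-target log-normal multiplier (SD ``batch_drift_sds``)
    scales all control/unknown quantities; with probability
    ``outlier_rate`` one well of a triplicate is displaced by 5-10
    cycles (random sign) and flagged in the returned truth.
    """
    if samples.empty:
        raise ValueError("run manifest must be nonempty")
    if control_ts is None:
        control_ts = control_true_ts(config)
    rng = _rng(config, 2, int(run_index))
    run_id = f"run{int(run_index):03d}"
    truth = GroundTruth(control_ts=dict(control_ts))
    mult = {
        t: float(np.exp(rng.normal(0.0, config.batch_drift_sds))) for t in ("T", "S")
    }
    truth.run_multipliers[run_id] = {**mult, "net": mult["T"] / mult["S"]}

    plates = {}
    for target in ("T", "S"):
        eff = config.true_efficiency_T if target == "T" else config.true_efficiency_S
        slope = slope_for_efficiency(eff)
        intercept = TRUE_INTERCEPT[target]
        rows: list[dict] = []
        widx = 0

        def add_well(sample_id: str, role: str, quantity_known: float, true_q: float):
            nonlocal widx
            cq = intercept + slope * math.log10(true_q) + rng.normal(0.0, config.cq_noise_sd)
            rows.append(
                {
                    "run_id": run_id,
                    "well": _well_name(widx),
                    "sample_id": sample_id,
                    "target": target,
                    "role": role,
                    "quantity_ng": quantity_known,
                    "cq": cq,
                }
            )
            widx += 1

        for q in STANDARD_SERIES_NG:
            for _ in range(3):
                add_well(f"std_{q:g}", "standard", q, q)

        triplicate_starts: list[int] = []
        for control in CONTROL_IDS:
            triplicate_starts.append(len(rows))
            t_over_s = control_ts[control]
            true_q = INPUT_DNA_NG * (t_over_s if target == "T" else 1.0) * mult[target]
            for _ in range(3):
                add_well(control, "control", np.nan, true_q)
        for rec in samples.itertuples(index=False):
            triplicate_starts.append(len(rows))
            true_q = INPUT_DNA_NG * (rec.true_ts if target == "T" else 1.0) * mult[target]
            for _ in range(3):
                add_well(rec.sample_id, "unknown", np.nan, true_q)

        # gross outlier wells: one well of an affected triplicate jumps 5-10 cycles
        for start in triplicate_starts:
            if rng.random() < config.outlier_rate:
                offset = int(rng.integers(3))
                shift = rng.uniform(5.0, 10.0) * (1.0 if rng.random() < 0.5 else -1.0)
                rows[start + offset]["cq"] += shift
                truth.outlier_wells.append((run_id, target, rows[start + offset]["well"]))
        plates[target] = pd.DataFrame(rows)

    return plates["T"], plates["S"], truth


def _split_ga(decimal_weeks: float) -> tuple[int, int]:
    total_days = int(round(decimal_weeks * 7.0))
    return total_days // 7, total_days % 7


def _progress(pseudo_ga: float) -> float:
    """Fraction of pregnancy elapsed: 0 at ~12 weeks, 1 from delivery on."""
    return float(np.clip((pseudo_ga - 12.0) / 28.0, 0.0, 1.0))


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cohort table, draw manifest, and planted truth.

    Each subject contributes 1-3 draws, one per gestational window
    (windows are never reused). True T/S follows
    ``baseline + within_person_drift * progress`` where progress runs 0
    to 1 over pregnancy; cesarean subjects' postpartum draws are shifted
    by ``cesarean_log_effect`` on the log scale; the latent sleep score
    shifts the whole trajectory by ``sleep_effect`` per unit score.
    """
    rng = _rng(config, 1)
    truth = GroundTruth(control_ts=control_true_ts(config))
    sd_log = config.baseline_log_sd
    cohort_rows = []
    draw_rows = []
    for i in range(config.n_subjects):
        subject = f"P{i + 1:03d}"
        present = rng.random(3) < np.array(_PRESENCE)
        while not present.any():
            present = rng.random(3) < np.array(_PRESENCE)
        age = float(rng.normal(29.8, 3.8))
        bmi = float(rng.normal(21.7, 2.8))
        race = str(rng.choice(_RACE_LEVELS, p=_RACE_PROBS))
        cesarean = bool(rng.random() < config.cesarean_rate)
        ga_delivery = float(np.clip(rng.normal(39.1, 1.3), 37.0, 41.0 + 6.0 / 7.0))
        del_w, del_d = _split_ga(ga_delivery)
        sleep = float(rng.normal(0.0, 1.0))
        truth.sleep_score[subject] = sleep
        epds = int(rng.negative_binomial(2.98, 2.98 / (2.98 + 4.4)))
        cohort_rows.append(
            {
                "subject_id": subject,
                "age": age,
                "bmi": bmi if rng.random() > 5 / 46 else np.nan,
                "race": race if rng.random() > 1 / 46 else np.nan,
                "private_insurance": int(rng.random() < 42 / 46),
                "college_degree": (
                    int(rng.random() < 0.878) if rng.random() > 5 / 46 else np.nan
                ),
                "spontaneous_conception": int(rng.random() < 41 / 46),
                "ga_delivery_weeks": del_w,
                "ga_delivery_days": del_d,
                "delivery_mode": "cesarean" if cesarean else "vaginal",
                "birthweight_g": (
                    float(rng.normal(3335, 411)) if rng.random() > 1 / 46 else np.nan
                ),
                "epds": epds if rng.random() > 0.34 else np.nan,
            }
        )

        log_base = rng.normal(math.log(config.baseline_ts_mean) - sd_log**2 / 2.0, sd_log)
        log_base += config.sleep_effect * sleep
        base = max(float(np.exp(log_base)), 0.3)
        for tp_index, has_draw in enumerate(present, start=1):
            if not has_draw:
                continue
            postpartum_days: int | None = None
            if tp_index == 1:
                ga = float(np.clip(rng.normal(12.0, 2.6), 5.0, 19.0 + 6.0 / 7.0))
                w, d = _split_ga(ga)
                pseudo = w + d / 7.0
            elif tp_index == 2:
                ga = float(np.clip(rng.normal(26.5, 1.8), 20.0 + 2.0 / 7.0, 36.0 + 6.0 / 7.0))
                w, d = _split_ga(ga)
                pseudo = w + d / 7.0
            else:
                if rng.random() < _POSTPARTUM_FRAC:
                    postpartum_days = int(rng.integers(7, 64))
                    w, d = del_w, del_d
                    pseudo = min(del_w + del_d / 7.0 + postpartum_days / 7.0, PSEUDO_GA_CAP)
                else:
                    ga = float(rng.uniform(37.0, max(ga_delivery, 37.01)))
                    w, d = _split_ga(ga)
                    pseudo = w + d / 7.0
            tp = assign_timepoint(w, d, postpartum_days)
            ts = (
                base
                + config.within_person_drift * _progress(pseudo)
                + rng.normal(0.0, config.visit_noise_sd)
            )
            if cesarean and postpartum_days is not None:
                ts = float(ts * math.exp(config.cesarean_log_effect))
            ts = max(ts, 0.05)
            sample_id = f"{subject}T{tp_index}"
            truth.true_ts[sample_id] = float(ts)
            draw_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "timepoint": tp,
                    "ga_weeks": w,
                    "ga_days": d,
                    "postpartum_days": postpartum_days,
                    "pseudo_ga": float(pseudo),
                }
            )
    cohort = pd.DataFrame(cohort_rows)
    draws = pd.DataFrame(draw_rows)
    draws["postpartum_days"] = draws["postpartum_days"].astype("Int64")
    return cohort, draws, truth


def simulate_plates(
    config: SimConfig,
    draws: pd.DataFrame,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plate wells for three measurement waves of every sample.

    Every sample is assayed in three independent runs (the pipeline uses
    the third wave only when the first two replicates are discordant).
    Samples are chunked into runs of ``config.samples_per_run``, shuffled
    per wave, and numbered consecutively so the first runs can serve as
    the control-reference batch.
    """
    sample_ids = draws["sample_id"].tolist()
    ctrl_ts = control_true_ts(config)
    plan_rng = _rng(config, 3)
    plates = []
    run_index = 1
    for _wave in range(3):
        order = plan_rng.permutation(len(sample_ids))
        for start in range(0, len(sample_ids), config.samples_per_run):
            chunk = [sample_ids[k] for k in order[start : start + config.samples_per_run]]
            manifest = pd.DataFrame(
                {"sample_id": chunk, "true_ts": [truth.true_ts[s] for s in chunk]}
            )
            plate_t, plate_s, slice_truth = simulate_plate_run(
                config, run_index, manifest, control_ts=ctrl_ts
            )
            truth.merge(slice_truth)
            plates.extend([plate_t, plate_s])
            run_index += 1
    return pd.concat(plates, ignore_index=True), truth


_FEATURE_KINDS = ("binary", "numeric", "categorical")
#: Cut points (z scale) coding a latent score into 4 ordered levels.
_CATEGORY_CUTS = (-0.6745, 0.0, 0.6745)
_N_LATENT_FACTORS = 8
_PRIMARY_LOADING = 0.75


def simulate_stress_survey(
    config: SimConfig,
    cohort: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> tuple[StressFeatureTable, GroundTruth]:
    """Mixed-type stress survey with a planted sleep-quality association.

    Features load on 8 latent factors (loadings fixed per seed) giving a
    correlated block structure; feature 0, ``f00_sleep_quality``, is the
    latent sleep score whose planted effect on log true T/S is
    ``config.sleep_effect``. Types cycle numeric / categorical (4
    levels) / binary; cells are masked missing at ``missing_rate``.
    """
    if cohort.empty:
        raise ValueError("cohort must be nonempty")
    n = len(cohort)
    subjects = cohort["subject_id"].tolist()
    rng = _rng(config, 4)
    load_rng = _rng(config, 5)
    if truth is None:
        truth = GroundTruth()
        truth.sleep_score = {
            s: float(v) for s, v in zip(subjects, rng.normal(0.0, 1.0, n))
        }
    factors = rng.normal(0.0, 1.0, size=(n, _N_LATENT_FACTORS))
    sleep = np.array([truth.sleep_score[s] for s in subjects], dtype=float)

    columns: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    names = []
    for j in range(config.n_features):
        if j == 0:
            name = "f00_sleep_quality"
            z = sleep.copy()
            kind = "numeric"
        else:
            factor = int(load_rng.integers(_N_LATENT_FACTORS))
            loading = _PRIMARY_LOADING
            noise_sd = math.sqrt(1.0 - loading**2)
            z = loading * factors[:, factor] + rng.normal(0.0, noise_sd, n)
            kind = _FEATURE_KINDS[j % 3]
            name = f"f{j:02d}_{kind}"
        if kind == "numeric":
            values = z
        elif kind == "categorical":
            values = np.digitize(z, _CATEGORY_CUTS).astype(float)
        else:
            values = (z > 0).astype(float)
        columns[name] = values
        types[name] = kind
        names.append(name)
        truth.feature_effects[name] = config.sleep_effect if j == 0 else 0.0

    data = pd.DataFrame(columns, index=pd.Index(subjects, name="subject_id"))
    if config.missing_rate > 0:
        mask = rng.random(data.shape) < config.missing_rate
        data = data.mask(mask)
    return StressFeatureTable(data=data, types=types), truth
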