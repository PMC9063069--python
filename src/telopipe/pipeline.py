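"""Pipeline orchestration, configuration, and file-format contracts.

Stages: simulate (optional) -> quantify -> adjust -> cohort -> screen.
All tables are plain UTF-8 CSV with a header row, "." decimals and empty
cells for missing values; gestational ages are serialized as separate
integer week and day columns, with the pseudo-gestational age as a
decimal-week column of its own. Results carry provenance metadata (a
hash of the configuration, the seed, and the package version) and are
fully determined by the configuration: runs with identical configs are
byte-identical.

Within a run the order of corrections is: per-run standard-curve
quantification with Dixon QC, then per-run batch adjustment of every
measurement, then the 7% duplicate-concordance rule and third-run
resolution on the *adjusted* values — replicates live on different runs,
so each must be corrected by its own run factor before they are compared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch import (
    NeedsThirdRunError,
    assay_cv,
    make_adjustment,
    build_reference,
    resolve_replicates,
)
from .cohort import (
    EmptyPairsError,
    completeness_range,
    delivery_mode_model,
    describe_cohort,
    paired_differences,
    rank_sum_by_mode,
)
from .quant import fit_standard_curve, quantify_sample
from .screen import (
    StressFeatureTable,
    correlation_network,
    cv_predict,
    impute_median,
    network_to_json,
    screen_features,
)
from .synth import GroundTruth, SimConfig, simulate_cohort, simulate_plates, simulate_stress_survey

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "quantify_plates",
    "adjust_measurements",
    "cohort_results",
    "screen_results",
]

_TIMEPOINT_PAIRS = ((1, 2), (2, 3), (1, 3))

_COHORT_DESCRIBE_VARS = {
    "age": "continuous",
    "bmi": "continuous",
    "race": "categorical",
    "private_insurance": "categorical",
    "college_degree": "categorical",
    "spontaneous_conception": "categorical",
    "delivery_mode": "categorical",
    "birthweight_g": "continuous",
}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    dixon_alpha: float = 0.05
    concordance_threshold: float = 0.07
    reference_run_count: int = 10
    screen_seed: int = 7
    perplexity: float | None = None
    cv_folds: int = 10
    cv_permutations: int = 100

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not 0.0 < self.concordance_threshold < 1.0 and self.concordance_threshold != 0.0:
            raise ValueError("concordance_threshold must be in [0, 1)")
        if not 0.0 < self.dixon_alpha < 1.0:
            raise ValueError("dixon_alpha must be in (0, 1)")
        if self.reference_run_count < 1:
            raise ValueError("reference_run_count must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def quantify_plates(
    plates: pd.DataFrame, dixon_alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(run, sample) raw T/S ratios from plate wells.

    Returns the quantification table (run_id, sample_id, role, raw_ts,
    t_quantity, s_quantity, wells removed by Dixon QC) and a per-run
    table of fitted standard curves.
    """
    quant_rows = []
    curve_rows = []
    for run_id, run_wells in plates.groupby("run_id", sort=True):
        curves = {}
        for target in ("T", "S"):
            standards = run_wells[
                (run_wells["target"] == target) & (run_wells["role"] == "standard")
            ]
            curves[target] = fit_standard_curve(
                list(zip(standards["quantity_ng"], standards["cq"])), target=target
            )
            curve_rows.append({"run_id": run_id, **asdict(curves[target])})
        others = run_wells[run_wells["role"] != "standard"]
        for (sample_id, role), group in others.groupby(["sample_id", "role"], sort=True):
            t_cqs = group.loc[group["target"] == "T", "cq"].to_numpy()
            s_cqs = group.loc[group["target"] == "S", "cq"].to_numpy()
            sq = quantify_sample(sample_id, t_cqs, s_cqs, curves["T"], curves["S"],
                                 alpha=dixon_alpha)
            t_qc, s_qc = sq.qc
            quant_rows.append(
                {
                    "run_id": run_id,
                    "sample_id": sample_id,
                    "role": role,
                    "raw_ts": sq.raw_ts,
                    "t_quantity": sq.t_quantity,
                    "s_quantity": sq.s_quantity,
                    "t_removed": t_qc.removed_index if t_qc else None,
                    "s_removed": s_qc.removed_index if s_qc else None,
                }
            )
    return pd.DataFrame(quant_rows), pd.DataFrame(curve_rows)


def adjust_measurements(
    quant: pd.DataFrame,
    reference_run_count: int = 10,
    concordance_threshold: float = 0.07,
) -> dict[str, Any]:
    """Batch-adjust every measurement, then resolve replicate pairs.

    Builds the control reference from the first ``reference_run_count``
    runs, converts raw to adjusted T/S per run, computes the control CV,
    and applies the 7% duplicate rule (third replicate used only when
    the first two are discordant) on adjusted values.
    """
    run_ids = sorted(quant["run_id"].unique())
    controls_by_run = {
        run: dict(
            zip(
                quant.loc[(quant["run_id"] == run) & (quant["role"] == "control"),
                          "sample_id"],
                quant.loc[(quant["run_id"] == run) & (quant["role"] == "control"),
                          "raw_ts"],
            )
        )
        for run in run_ids
    }
    reference = build_reference(
        [controls_by_run[r] for r in run_ids[:reference_run_count]],
        expected_runs=reference_run_count,
    )
    adjustments = {
        run: make_adjustment(run, controls_by_run[run], reference) for run in run_ids
    }
    adjusted = quant.copy()
    adjusted["run_factor"] = adjusted["run_id"].map(
        {run: adj.run_factor for run, adj in adjustments.items()}
    )
    adjusted["adjusted_ts"] = adjusted["raw_ts"] * adjusted["run_factor"]

    control_history = {
        c: adjusted.loc[
            (adjusted["role"] == "control") & (adjusted["sample_id"] == c), "adjusted_ts"
        ].tolist()
        for c in reference
    }
    qc = assay_cv(control_history)

    replicate_rows = []
    unknowns = adjusted[adjusted["role"] == "unknown"].sort_values("run_id")
    for sample_id, group in unknowns.groupby("sample_id", sort=True):
        values = group["adjusted_ts"].tolist()
        runs = group["run_id"].tolist()
        if len(values) == 1:
            replicate_rows.append(
                {"sample_id": sample_id, "reported_ts": values[0], "concordant": True,
                 "n_measured": 1, "runs_used": runs[0]}
            )
            continue
        try:
            rs = resolve_replicates(values[:2], runs[:2], threshold=concordance_threshold)
            n_measured = 2
        except NeedsThirdRunError:
            if len(values) < 3:
                replicate_rows.append(
                    {"sample_id": sample_id, "reported_ts": np.nan, "concordant": False,
                     "n_measured": 2, "runs_used": ""}
                )
                continue
            rs = resolve_replicates(values[:3], runs[:3], threshold=concordance_threshold)
            n_measured = 3
        replicate_rows.append(
            {
                "sample_id": sample_id,
                "reported_ts": rs.reported_ts,
                "concordant": rs.concordant,
                "n_measured": n_measured,
                "runs_used": "+".join(rs.runs_used),
            }
        )
    return {
        "adjusted": adjusted,
        "replicates": pd.DataFrame(replicate_rows),
        "adjustments": adjustments,
        "reference": reference,
        "assay_qc": qc,
    }


def _ltl_table(replicates: pd.DataFrame, draws: pd.DataFrame) -> pd.DataFrame:
    merged = draws.merge(replicates[["sample_id", "reported_ts"]], on="sample_id")
    merged = merged.rename(columns={"reported_ts": "ts"}).dropna(subset=["ts"])
    return merged


def cohort_results(
    replicates: pd.DataFrame, draws: pd.DataFrame, cohort: pd.DataFrame
) -> dict[str, Any]:
    """Longitudinal comparisons, delivery-mode analysis, descriptives."""
    ltl = _ltl_table(replicates, draws)
    paired = {}
    for pair in _TIMEPOINT_PAIRS:
        try:
            paired[f"t{pair[0]}_vs_t{pair[1]}"] = paired_differences(ltl, pair)
        except EmptyPairsError:
            paired[f"t{pair[0]}_vs_t{pair[1]}"] = None

    timepoint_means = {
        int(tp): {"n": int(g.size), "mean": float(g.mean()),
                  "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0}
        for tp, g in ltl.groupby("timepoint")["ts"]
    }

    postpartum = ltl[(ltl["timepoint"] == 3) & ltl["postpartum_days"].notna()]
    postpartum = postpartum.merge(
        cohort[["subject_id", "delivery_mode", "age"]], on="subject_id"
    )
    mode_comparison = None
    mode_model = None
    if postpartum["delivery_mode"].nunique() == 2:
        w, p, sizes = rank_sum_by_mode(postpartum["ts"], postpartum["delivery_mode"])
        groups = {
            m: {"n": int(g.size), "mean": float(g.mean()),
                "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0}
            for m, g in postpartum.groupby("delivery_mode")["ts"]
        }
        mode_comparison = {"statistic": w, "p_value": p, "sizes": sizes, "groups": groups}
        if min(sizes.values()) >= 3:
            mode_model = delivery_mode_model(
                postpartum["ts"],
                postpartum["age"],
                (postpartum["delivery_mode"] == "cesarean").astype(int),
            )
    described = describe_cohort(cohort, _COHORT_DESCRIBE_VARS)
    return {
        "ltl": ltl,
        "timepoint_means": timepoint_means,
        "paired": paired,
        "mode_comparison": mode_comparison,
        "mode_model": mode_model,
        "descriptive": described,
    }


def subject_outcomes(ltl: pd.DataFrame) -> pd.DataFrame:
    """Per-subject screening outcomes: Timepoint 1 LTL and mean LTL."""
    t1 = ltl[ltl["timepoint"] == 1].groupby("subject_id")["ts"].mean()
    mean = ltl.groupby("subject_id")["ts"].mean()
    return pd.DataFrame({"t1_ltl": t1, "mean_ltl": mean})


def screen_results(
    survey: StressFeatureTable,
    outcomes: pd.DataFrame,
    seed: int = 7,
    perplexity: float | None = None,
    cv_folds: int = 10,
    cv_permutations: int = 100,
) -> dict[str, Any]:
    """Univariate screen, correlation network, and SVM cross-validation

    for each outcome (Timepoint 1 LTL and mean LTL), on the same imputed
    feature table.
    """
    complete = impute_median(survey)
    out: dict[str, Any] = {"completeness": completeness_range(survey.data, len(survey.data))}
    for outcome_name, series in (("t1", outcomes["t1_ltl"]), ("mean", outcomes["mean_ltl"])):
        associations = screen_features(survey, series)
        graph = correlation_network(
            complete, associations, embed_seed=seed, perplexity=perplexity
        )
        n_subjects = int(series.reindex(survey.data.index).notna().sum())
        cv = None
        if n_subjects >= cv_folds:
            cv = cv_predict(
                survey, series, folds=cv_folds, seed=seed, n_permutations=cv_permutations
            )
        out[outcome_name] = {
            "associations": associations,
            "network": graph,
            "cv": cv,
            "n_subjects": n_subjects,
        }
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Simulate -> quantify -> adjust -> cohort -> screen, end to end.

    Returns the results bundle; when ``outdir`` is given, writes all
    stage tables and JSON results there (removing partial outputs if any
    stage fails).
    """
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        if outdir is None:
            return
        path = Path(outdir) / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        written.append(path)

    try:
        cohort, draws, truth = simulate_cohort(config.sim)
        survey, truth = simulate_stress_survey(config.sim, cohort, truth)
        plates, truth = simulate_plates(config.sim, draws, truth)
        emit("cohort.csv", lambda p: cohort.to_csv(p, index=False))
        emit("draws.csv", lambda p: draws.to_csv(p, index=False))
        emit("plates.csv", lambda p: plates.to_csv(p, index=False))
        emit("survey.csv", lambda p: survey.data.to_csv(p))
        emit(
            "survey_types.json",
            lambda p: p.write_text(json.dumps(survey.types, indent=1)),
        )
        emit(
            "truth.json",
            lambda p: p.write_text(json.dumps(_jsonable(truth.to_dict()), indent=1)),
        )

        quant, curves = quantify_plates(plates, dixon_alpha=config.dixon_alpha)
        emit("quant.csv", lambda p: quant.to_csv(p, index=False))
        emit("curves.csv", lambda p: curves.to_csv(p, index=False))

        batch_out = adjust_measurements(
            quant,
            reference_run_count=config.reference_run_count,
            concordance_threshold=config.concordance_threshold,
        )
        emit("adjusted.csv", lambda p: batch_out["adjusted"].to_csv(p, index=False))
        emit("replicates.csv", lambda p: batch_out["replicates"].to_csv(p, index=False))

        cohort_out = cohort_results(batch_out["replicates"], draws, cohort)
        emit(
            "descriptive.csv", lambda p: cohort_out["descriptive"].to_csv(p, index=False)
        )

        outcomes = subject_outcomes(cohort_out["ltl"])
        screen_out = screen_results(
            survey,
            outcomes,
            seed=config.screen_seed,
            perplexity=config.perplexity,
            cv_folds=config.cv_folds,
            cv_permutations=config.cv_permutations,
        )
        for outcome_name in ("t1", "mean"):
            graph = screen_out[outcome_name]["network"]
            emit(
                f"network_{outcome_name}.json",
                lambda p, g=graph: p.write_text(json.dumps(_jsonable(network_to_json(g)), indent=1)),
            )

        results = {
            "provenance": {
                "config_hash": config.config_hash(),
                "seed": config.sim.seed,
                "version": __version__,
            },
            "efficiency": {
                t: float(curves.loc[curves["target"] == t, "efficiency"].mean())
                for t in ("T", "S")
            },
            "cv_percent": batch_out["assay_qc"].cv_percent,
            "timepoint_means": cohort_out["timepoint_means"],
            "paired": {k: v for k, v in cohort_out["paired"].items()},
            "mode_comparison": cohort_out["mode_comparison"],
            "mode_model": cohort_out["mode_model"],
            "completeness": screen_out["completeness"],
            "screen": {
                name: {
                    "n_subjects": screen_out[name]["n_subjects"],
                    "n_significant": sum(
                        a.p_value < 0.05 for a in screen_out[name]["associations"]
                    ),
                    "sleep_p": next(
                        a.p_value
                        for a in screen_out[name]["associations"]
                        if a.feature == "f00_sleep_quality"
                    ),
                    "cv_r2": (
                        screen_out[name]["cv"].r2 if screen_out[name]["cv"] else None
                    ),
                    "cv_significant": (
                        screen_out[name]["cv"].significant
                        if screen_out[name]["cv"]
                        else None
                    ),
                }
                for name in ("t1", "mean")
            },
        }
        emit(
            "results.json", lambda p: p.write_text(json.dumps(_jsonable(results), indent=1))
        )
        bundle = {
            "results": results,
            "truth": truth,
            "tables": {
                "cohort": cohort,
                "draws": draws,
                "plates": plates,
                "quant": quant,
                "curves": curves,
                "adjusted": batch_out["adjusted"],
                "replicates": batch_out["replicates"],
                "ltl": cohort_out["ltl"],
                "descriptive": cohort_out["descriptive"],
            },
            "survey": survey,
            "screen": screen_out,
            "cohort_analysis": cohort_out,
            "batch": batch_out,
        }
        return bundle
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        raise
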