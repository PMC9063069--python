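import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telopipe.cohort import assign_timepoint
from telopipe.quant import fit_standard_curve
from telopipe.synth import (
    CONTROL_IDS,
    STANDARD_SERIES_NG,
    SimConfig,
    simulate_cohort,
    simulate_dilution_series,
    simulate_plate_run,
    simulate_plates,
    simulate_stress_survey,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"outlier_rate": 1.5},
            {"cq_noise_sd": -0.1},
            {"n_subjects": 0},
            {"true_efficiency_T": 1.5},
            {"missing_rate": -0.2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDilutionSeries:
    def test_exact_doubling_chemistry(self):
        wells = simulate_dilution_series(-3.321928, 30.0, (10, 1, 0.1), noise_sd=0.0)
        cqs = [cq for _, cq in wells]
        assert cqs == pytest.approx([26.678072, 30.0, 33.321928], abs=1e-6)

    def test_roundtrip_any_slope_through_printed_series(self):
        for slope in (-3.1, -3.45, -3.9):
            wells = simulate_dilution_series(slope, 25.0, STANDARD_SERIES_NG, noise_sd=0.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = fit_standard_curve(wells)
            assert curve.slope == pytest.approx(slope, abs=1e-12)

    def test_monte_carlo_slope_unbiased(self):
        """Fitted slopes over noisy replicates center on the truth
        (least-squares oracle: mean within 3 SE)."""
        slopes = []
        for rep in range(100):
            wells = simulate_dilution_series(
                -3.5, 28.0, STANDARD_SERIES_NG, noise_sd=0.05, seed=1000 + rep
            )
            q = np.log10([w[0] for w in wells])
            cq = [w[1] for w in wells]
            slopes.append(stats.linregress(q, cq).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - (-3.5)) < 3 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_dilution_series(-3.3, 30.0, (1.0, -2.0))
        with pytest.raises(ValueError):
            simulate_dilution_series(-3.3, 30.0, (1.0, 1.0))


class TestPlateRun:
    @staticmethod
    def _manifest(n=5):
        return pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "true_ts": np.linspace(0.8, 1.4, n)}
        )

    def test_plate_layout(self):
        t, s, truth = simulate_plate_run(SimConfig(seed=1), 1, self._manifest())
        for plate, target in ((t, "T"), (s, "S")):
            assert set(plate["target"]) == {target}
            stds = plate[plate["role"] == "standard"]
            assert sorted(stds["quantity_ng"].unique()) == sorted(STANDARD_SERIES_NG)
            assert (stds.groupby("quantity_ng").size() == 3).all()
            ctrls = plate[plate["role"] == "control"]
            assert set(ctrls["sample_id"]) == set(CONTROL_IDS)
            assert (plate[plate["role"] != "standard"].groupby("sample_id").size() == 3).all()
            assert plate["well"].is_unique

    def test_no_outliers_when_rate_zero(self):
        _, _, truth = simulate_plate_run(
            SimConfig(seed=2, outlier_rate=0.0), 1, self._manifest()
        )
        assert truth.outlier_wells == []

    def test_outlier_count_binomially_consistent(self):
        config = SimConfig(seed=3, outlier_rate=0.1, samples_per_run=100)
        manifest = self._manifest(42)  # (42 + 8 controls) x 2 targets = 100 triplicates
        _, _, truth = simulate_plate_run(config, 1, manifest)
        flagged = len(truth.outlier_wells)
        assert stats.binomtest(flagged, 100, 0.1).pvalue > 0.001

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate_run(SimConfig(seed=1), 1, pd.DataFrame(columns=["sample_id"]))


class TestCohortSimulation:
    def test_draw_windows_and_truth_completeness(self):
        config = SimConfig(seed=4, n_subjects=60)
        cohort, draws, truth = simulate_cohort(config)
        assert len(cohort) == 60
        # every draw has a truth entry and lies in exactly the window of
        # its recorded timepoint
        for row in draws.itertuples():
            assert row.sample_id in truth.true_ts
            pp = None if pd.isna(row.postpartum_days) else int(row.postpartum_days)
            assert assign_timepoint(row.ga_weeks, row.ga_days, pp) == row.timepoint
            assert 0 <= row.pseudo_ga <= 50
        per_subject = draws.groupby("subject_id").size()
        assert per_subject.between(1, 3).all()
        assert truth.true_ts.keys() == set(draws["sample_id"])

    def test_null_generator_has_unbiased_paired_differences(self):
        from telopipe.cohort import paired_differences

        config = SimConfig(
            seed=5, n_subjects=200, within_person_drift=0.0, cesarean_log_effect=0.0
        )
        _, draws, truth = simulate_cohort(config)
        ltl = draws.assign(ts=draws["sample_id"].map(truth.true_ts))
        cmp13 = paired_differences(ltl, (1, 3))
        se = cmp13.sd_diff / np.sqrt(cmp13.n_pairs)
        assert abs(cmp13.mean_diff) < 2 * se

    def test_cesarean_rate_binomially_consistent(self):
        total = 0
        n_sims, n = 50, 46
        for seed in range(100, 100 + n_sims):
            cohort, _, _ = simulate_cohort(SimConfig(seed=seed, n_subjects=n))
            total += (cohort["delivery_mode"] == "cesarean").sum()
        assert stats.binomtest(total, n_sims * n, 0.391).pvalue > 0.001

    def test_cross_sectional_spread_matches_target(self):
        config = SimConfig(seed=6, n_subjects=3000, sleep_effect=0.0)
        _, draws, truth = simulate_cohort(config)
        t1 = draws[draws["timepoint"] == 1]
        vals = t1["sample_id"].map(truth.true_ts)
        assert vals.mean() == pytest.approx(config.baseline_ts_mean, abs=0.02)
        assert vals.std() == pytest.approx(config.baseline_ts_sd, abs=0.02)


class TestStressSurvey:
    def test_shape_types_and_planted_effect(self):
        config = SimConfig(seed=7, n_subjects=40)
        cohort, draws, truth = simulate_cohort(config)
        survey, truth = simulate_stress_survey(config, cohort, truth)
        assert survey.data.shape == (40, 79)
        assert set(survey.types.values()) <= {"numeric", "categorical", "binary"}
        assert survey.types["f00_sleep_quality"] == "numeric"
        effects = truth.feature_effects
        assert effects["f00_sleep_quality"] == config.sleep_effect
        assert sum(v != 0 for v in effects.values()) == 1
        binary_cols = [c for c, t in survey.types.items() if t == "binary"]
        assert all(survey.data[c].dropna().nunique() <= 2 for c in binary_cols)

    def test_missingness_binomially_consistent(self):
        config = SimConfig(seed=8, n_subjects=50, missing_rate=0.1)
        cohort, _, truth = simulate_cohort(config)
        survey, _ = simulate_stress_survey(config, cohort, truth)
        n_missing = int(survey.data.isna().sum().sum())
        assert stats.binomtest(n_missing, survey.data.size, 0.1).pvalue > 0.001

    def test_null_sleep_pvalues_uniform(self):
        """With no planted effect, the sleep-feature association p-values
        are U(0,1) (KS calibration over 200 simulated cohorts)."""
        from telopipe.screen import univariate_association

        pvals = []
        for seed in range(200):
            config = SimConfig(seed=seed, n_subjects=27, sleep_effect=0.0)
            cohort, draws, truth = simulate_cohort(config)
            survey, truth = simulate_stress_survey(config, cohort, truth)
            t1 = draws[draws["timepoint"] == 1].set_index("subject_id")
            y = t1["sample_id"].map(truth.true_ts)
            y = y.reindex(survey.data.index)
            res = univariate_association(
                survey.data["f00_sleep_quality"], y, kind="numeric"
            )
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        config = SimConfig(seed=11, n_subjects=10)
        out = []
        for _ in range(2):
            cohort, draws, truth = simulate_cohort(config)
            survey, truth = simulate_stress_survey(config, cohort, truth)
            plates, truth = simulate_plates(config, draws, truth)
            out.append(
                cohort.to_csv() + draws.to_csv() + survey.data.to_csv() + plates.to_csv()
            )
        assert out[0] == out[1]

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimConfig(seed=1, n_subjects=10))[0]
        b = simulate_cohort(SimConfig(seed=2, n_subjects=10))[0]
        assert not a.equals(b)
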