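"""Cohort generation, measurement, correlation and the experiment driver."""

import json

import numpy as np
import pytest
from scipy.stats import t as student_t

import dualhorizon as dh
from dualhorizon.cohort import ObserverSpread, load_config

NO_JITTER = ObserverSpread(sigma_sd=0.0, criterion_sd=0.0)


class TestGenerateCohort:
    def test_default_design(self):
        cohort = dh.generate_cohort(seed=1)
        assert len(cohort) == 9
        assert all(-2.5 <= s.lambda_affected <= 2.0 for s in cohort)
        assert all(s.lambda_fellow == 0.0 for s in cohort)

    def test_degenerate_range_gives_untorted_cohort(self):
        cohort = dh.generate_cohort(n=3, torsion_range=(0.0, 0.0), seed=0)
        assert all(s.lambda_affected == 0.0 for s in cohort)

    def test_seeded_determinism(self):
        a = dh.generate_cohort(seed=7)
        b = dh.generate_cohort(seed=7)
        assert a == b
        c = dh.generate_cohort(seed=8)
        assert a != c

    def test_too_small_cohort_rejected(self):
        with pytest.raises(dh.CohortTooSmallError):
            dh.generate_cohort(n=2)


class TestPearson:
    def test_perfect_linearity(self):
        res = dh.pearson([1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0, 9.0])
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_hand_computed_example(self):
        res = dh.pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert res.r == pytest.approx(0.5, abs=1e-12)

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        res = dh.pearson(x, y)
        tval = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        p_hand = 2 * student_t.sf(abs(tval), df=res.n - 2)
        assert res.p == pytest.approx(p_hand, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(dh.UndefinedCorrelationError):
            dh.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(dh.UndefinedCorrelationError):
            dh.pearson([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMeasureCohort:
    def test_analytic_thresholds_increase_with_torsion(self, calib):
        cohort = dh.generate_cohort(seed=3, observer_spread=NO_JITTER)
        res = dh.measure_cohort(cohort, mode="analytic", seed=3)
        aff = res.records[(res.records.eye == "affected")
                          & (res.records.axis == "horizontal")]
        ordered = aff.sort_values("lambda_deg").ir_threshold.to_numpy()
        assert np.all(np.diff(ordered) > 0)

    def test_fellow_eye_identical_without_jitter(self, calib):
        cohort = dh.generate_cohort(seed=3, observer_spread=NO_JITTER)
        res = dh.measure_cohort(cohort, mode="analytic", seed=3)
        fellow = res.records[(res.records.eye == "fellow")
                             & (res.records.axis == "horizontal")]
        assert fellow.ir_threshold.nunique() == 1
        # the degenerate fellow correlation is reported as NaN, not an error
        assert np.isnan(res.correlation_fellow.r)

    def test_analytic_no_jitter_correlation_near_perfect(self, calib):
        cohort = dh.generate_cohort(seed=5, observer_spread=NO_JITTER)
        res = dh.measure_cohort(cohort, mode="analytic", seed=5)
        assert res.correlation_affected.r > 0.99
        assert res.correlation_affected.n == 9

    def test_staircase_mode_reproducible(self, calib):
        cohort = dh.generate_cohort(seed=2)
        a = dh.measure_cohort(cohort, mode="staircase", seed=2)
        b = dh.measure_cohort(cohort, mode="staircase", seed=2)
        assert a.records.equals(b.records)
        assert a.correlation_affected == b.correlation_affected

    def test_record_layout(self, calib):
        cohort = dh.generate_cohort(n=4, seed=1)
        res = dh.measure_cohort(cohort, mode="analytic", seed=1)
        # one record per subject x eye x axis
        assert len(res.records) == 4 * 2 * 2
        assert res.correlation_affected.n == 4
        assert res.correlation_fellow.n == 4
        assert res.n_excluded == 0

    def test_invalid_mode_rejected(self):
        cohort = dh.generate_cohort(n=3, seed=0)
        with pytest.raises(dh.ConfigurationError):
            dh.measure_cohort(cohort, mode="bayesian")


class TestConfigAndDriver:
    def test_defaults_validate(self):
        cfg = load_config()
        assert cfg["n_subjects"] == 9
        assert cfg["torsion_range"] == [-2.5, 2.0]

    def test_unknown_field_diagnosed(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("observr: {sigma: 2}\n")
        with pytest.raises(dh.ConfigurationError, match="observr"):
            load_config(path)

    def test_bad_value_diagnosed_with_field_path(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("observer:\n  sigma: -1\n")
        with pytest.raises(dh.ConfigurationError, match="observer.sigma"):
            load_config(path)

    def test_unordered_torsion_range_diagnosed(self):
        with pytest.raises(dh.ConfigurationError, match="torsion_range"):
            load_config(overrides={"torsion_range": [2.0, -2.5]})

    def test_json_config_accepted(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"mode": "analytic", "n_subjects": 4}))
        cfg = load_config(path)
        assert cfg["mode"] == "analytic"
        assert cfg["n_subjects"] == 4

    def test_run_experiment_writes_outputs(self, tmp_path, calib):
        summary = dh.run_experiment(
            config={"mode": "analytic", "n_subjects": 5},
            out_dir=tmp_path / "out",
            seed=11,
        )
        assert summary["correlation_affected"]["n"] == 5
        written = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert written["correlation_affected"] == summary["correlation_affected"]
        assert (tmp_path / "out" / "cohort.csv").exists()
        assert (tmp_path / "out" / "thresholds.csv").exists()

    def test_run_experiment_staircase_writes_trial_log(self, tmp_path, calib):
        summary = dh.run_experiment(
            config={"mode": "staircase", "n_subjects": 3},
            out_dir=tmp_path / "out",
            seed=4,
        )
        assert (tmp_path / "out" / "trials.csv").exists()
        assert summary["correlation_affected"]["n"] == 3
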