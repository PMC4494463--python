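"""Forced-choice observer: classification, response statistics, analytic oracle."""

import numpy as np
import pytest
from scipy.stats import norm

import dualhorizon as dh

# central normal mass within +/-1.5 sd and one tail beyond it
P_CIRCLE_AT_ZERO = 2 * norm.cdf(1.5) - 1          # 0.86638...
P_TAIL_AT_ZERO = 1 - norm.cdf(1.5)                # 0.06680...


class TestClassify:
    @pytest.mark.parametrize(
        "percept, criterion, expected",
        [
            (+5.0, 3.0, "horizontal"),
            (-5.0, 3.0, "vertical"),
            (+1.0, 3.0, "circle"),
            (+3.0, 3.0, "circle"),   # boundary equality -> circle
            (-3.0, 3.0, "circle"),
        ],
    )
    def test_partition(self, percept, criterion, expected):
        assert dh.classify(percept, criterion) == expected


class TestRespond:
    def test_noiseless_circle_always_circle(self, calib):
        params = dh.ObserverParams(sigma=1e-9, criterion=3.0)
        stim = dh.EllipseStimulus(300.0, 300.0)
        rng = np.random.default_rng(0)
        responses = {
            dh.respond(stim, dh.TorsionState(0.0), params, rng, calib=calib)
            for _ in range(20)
        }
        assert responses == {"circle"}

    def test_seeded_determinism(self, calib, default_params):
        stim = dh.stimulus_from_ir(3.0, 300.0)
        tors = dh.TorsionState(1.0)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            runs.append(
                [dh.respond(stim, tors, default_params, rng, calib=calib)
                 for _ in range(20)]
            )
        assert runs[0] == runs[1]


class TestResponseProbabilities:
    def test_symmetry_and_frozen_values_at_zero_percept(self, calib):
        params = dh.ObserverParams(sigma=2.0, criterion=3.0)
        stim = dh.EllipseStimulus(300.0, 300.0)
        probs = dh.response_probabilities(stim, dh.TorsionState(0.0), params, calib)
        assert probs["horizontal"] == pytest.approx(probs["vertical"], abs=1e-12)
        assert probs["circle"] == pytest.approx(P_CIRCLE_AT_ZERO, abs=1e-9)
        assert probs["horizontal"] == pytest.approx(P_TAIL_AT_ZERO, abs=1e-9)

    @pytest.mark.parametrize("ir, lam", [(0.0, 0.0), (5.0, 1.0), (-8.0, -2.0)])
    def test_probabilities_sum_to_one(self, calib, ir, lam):
        params = dh.ObserverParams()
        stim = dh.stimulus_from_ir(ir, 300.0)
        probs = dh.response_probabilities(stim, dh.TorsionState(lam), params, calib)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("ir, lam, sigma", [(0.0, 0.0, 2.0), (4.0, 1.5, 1.0),
                                                (-6.0, -2.0, 3.0)])
    def test_matches_monte_carlo(self, calib, ir, lam, sigma):
        """Closed-form category probabilities vs 1e5 simulated trials."""
        params = dh.ObserverParams(sigma=sigma, criterion=3.0)
        stim = dh.stimulus_from_ir(ir, 300.0) if ir else dh.EllipseStimulus(300.0, 300.0)
        tors = dh.TorsionState(lam)
        probs = dh.response_probabilities(stim, tors, params, calib)
        mu = dh.perceived_ir(stim, tors, calib)
        rng = np.random.default_rng(7)
        draws = mu + sigma * rng.standard_normal(100_000)
        freq = {
            "horizontal": np.mean(draws > params.criterion),
            "vertical": np.mean(draws < -params.criterion),
        }
        freq["circle"] = 1.0 - freq["horizontal"] - freq["vertical"]
        for cat in ("circle", "horizontal", "vertical"):
            se = np.sqrt(probs[cat] * (1 - probs[cat]) / 100_000)
            assert abs(freq[cat] - probs[cat]) < 3 * max(se, 1e-4)

    def test_small_sample_respond_frequencies(self, calib):
        # the trial-level sampler agrees with its own closed form
        params = dh.ObserverParams(sigma=2.0, criterion=3.0)
        stim = dh.stimulus_from_ir(4.0, 300.0)
        tors = dh.TorsionState(0.0)
        rng = np.random.default_rng(11)
        n = 4000
        count = sum(
            dh.respond(stim, tors, params, rng, calib=calib) == "horizontal"
            for _ in range(n)
        )
        p = dh.p_response("horizontal", stim, tors, params, calib)
        assert abs(count / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestAnalyticThreshold:
    def test_untorted_half_point_sits_at_criterion(self, calib):
        # at lambda=0 the percept is the identity, so P(correct)=0.5 at the
        # criterion regardless of sigma
        for sigma in (1e-6, 2.0):
            params = dh.ObserverParams(sigma=sigma, criterion=3.0)
            thr = dh.analytic_threshold(
                "horizontal", dh.TorsionState(0.0), params, calib=calib
            )
            assert thr == pytest.approx(3.0, abs=1e-5)

    def test_incyclo_raises_horizontal_threshold(self, calib, default_params):
        t0 = dh.analytic_threshold("horizontal", dh.TorsionState(0.0),
                                   default_params, calib=calib)
        t_in = dh.analytic_threshold("horizontal", dh.TorsionState(+2.0),
                                     default_params, calib=calib)
        t_ex = dh.analytic_threshold("horizontal", dh.TorsionState(-2.0),
                                     default_params, calib=calib)
        assert t_ex < t0 < t_in

    def test_axis_thresholds_move_oppositely(self, calib, default_params):
        lams = [-2.5, -1.0, 0.0, 1.0, 2.0]
        horiz = [dh.analytic_threshold("horizontal", dh.TorsionState(l),
                                       default_params, calib=calib) for l in lams]
        vert = [dh.analytic_threshold("vertical", dh.TorsionState(l),
                                      default_params, calib=calib) for l in lams]
        assert np.all(np.diff(horiz) > 0)
        assert np.all(np.diff(vert) < 0)

    def test_monotone_in_sigma_and_criterion(self, calib):
        tors = dh.TorsionState(0.0)
        # strictly increasing in sigma above the 50% tracking level
        thr_sigma = [
            dh.analytic_threshold(
                "horizontal", tors, dh.ObserverParams(sigma=s, criterion=3.0),
                p_target=0.75, calib=calib)
            for s in (1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(thr_sigma) > 0)
        # non-decreasing in sigma at the tracked 50% level
        thr_sigma_50 = [
            dh.analytic_threshold(
                "horizontal", tors, dh.ObserverParams(sigma=s, criterion=3.0),
                calib=calib)
            for s in (1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(thr_sigma_50) >= -1e-9)
        # strictly increasing in the criterion at fixed sigma
        thr_crit = [
            dh.analytic_threshold(
                "horizontal", tors, dh.ObserverParams(sigma=2.0, criterion=c),
                calib=calib)
            for c in (1.0, 3.0, 5.0)
        ]
        assert np.all(np.diff(thr_crit) > 0)

    def test_unreachable_target_raises(self, calib):
        params = dh.ObserverParams(sigma=50.0, criterion=55.0)
        with pytest.raises(dh.ThresholdOutOfRangeError):
            dh.analytic_threshold(
                "horizontal", dh.TorsionState(0.0), params, p_target=0.9, calib=calib
            )

    def test_invalid_p_target_rejected(self, calib, default_params):
        with pytest.raises(dh.InvalidParameterError):
            dh.analytic_threshold(
                "horizontal", dh.TorsionState(0.0), default_params,
                p_target=1.0, calib=calib
            )


class TestObserverParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma": 0.0},
            {"criterion": -1.0},
            {"gain": -0.1},
            {"lapse_rate": 1.0},
        ],
    )
    def test_domain_validation(self, kwargs):
        with pytest.raises(dh.InvalidParameterError):
            dh.ObserverParams(**kwargs)
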