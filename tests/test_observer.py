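"""Observer models: conflict geometry, response model, simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtr

from avbisect import (
    ObserverParams,
    TaskDesign,
    TrialRecord,
    TrialSpec,
    cue_offsets,
    response_probability,
    simulate_responses,
    simulate_session,
    simulate_training_screen,
    simulate_trial,
)


class TestCueOffsets:
    @pytest.mark.parametrize(
        "domain, conflict, x, expected",
        [
            ("time", 50.0, 0.0, (0.0, 100.0)),     # outer −Δ shifts double the probe conflict
            ("space", 4.5, 0.0, (4.5, -4.5)),      # visual +Δ, auditory −Δ
            ("time", 0.0, 7.0, (7.0, 7.0)),        # zero conflict: cues agree
            ("space", 0.0, 7.0, (7.0, 7.0)),
            ("time", -50.0, 10.0, (10.0, -90.0)),
        ],
    )
    def test_conflict_geometry(self, domain, conflict, x, expected):
        spec = TrialSpec(domain, "bimodal", conflict, x)
        assert cue_offsets(spec) == pytest.approx(expected)

    @given(
        x=st.floats(-500, 500),
        dx=st.floats(-100, 100),
        conflict=st.sampled_from([-50.0, 0.0, 50.0]),
        domain=st.sampled_from(["time", "space"]),
    )
    def test_linear_in_probe_offset_with_unit_slope(self, x, dx, conflict, domain):
        a = cue_offsets(TrialSpec(domain, "bimodal", conflict, x))
        b = cue_offsets(TrialSpec(domain, "bimodal", conflict, x + dx))
        assert b[0] - a[0] == pytest.approx(dx, abs=1e-9)
        assert b[1] - a[1] == pytest.approx(dx, abs=1e-9)


class TestTrialSpecValidation:
    def test_unimodal_conflict_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec("time", "visual", conflict=50.0)

    def test_nonfinite_offset_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec("time", "bimodal", 50.0, float("inf"))

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec("frequency", "visual")
        with pytest.raises(ValueError):
            TrialSpec("time", "tactile")


class TestObserverParamsValidation:
    def test_lapse_bounds(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_v=1, sigma_a=1, lapse=0.2)

    def test_positive_sigmas_required(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_v=-1, sigma_a=1)

    def test_fixed_weights_needs_w_a(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_v=1, sigma_a=1, rule="fixed_weights")


class TestResponseProbability:
    def test_saturates_far_from_pse(self):
        p = ObserverParams(sigma_v=1.0, sigma_a=1.0)
        spec = TrialSpec("time", "visual", 0.0, 1e6)
        assert response_probability(spec, p) == pytest.approx(1.0)

    def test_auditory_capture_indifferent_at_auditory_midpoint(self):
        # e = w_A (x + 2Δ) = 0 at x = −2Δ
        p = ObserverParams(sigma_v=1.0, sigma_a=50.0, rule="auditory_capture")
        spec = TrialSpec("time", "bimodal", 50.0, -100.0)
        assert response_probability(spec, p) == pytest.approx(0.5)

    def test_optimal_combined_sigma_matches_closed_form(self):
        # σ_eff = 1/√2 for two unit-σ cues; at x = 1/√2 the probability is Φ(1)
        p = ObserverParams(sigma_v=1.0, sigma_a=1.0, rule="optimal")
        spec = TrialSpec("space", "bimodal", 0.0, 2**-0.5)
        assert response_probability(spec, p) == pytest.approx(ndtr(1.0), abs=1e-12)

    def test_monte_carlo_frequency_matches_probability(self, rng):
        p = ObserverParams(sigma_v=1.0, sigma_a=1.0, rule="optimal")
        spec = TrialSpec("space", "bimodal", 0.0, 2**-0.5)
        n = 100_000
        freq = simulate_responses(spec, p, n, rng).mean()
        prob = ndtr(1.0)
        assert abs(freq - prob) < 3 * np.sqrt(prob * (1 - prob) / n)

    @pytest.mark.parametrize(
        "rule, kwargs",
        [
            ("optimal", {}),
            ("visual_capture", {}),
            ("auditory_capture", {}),
            ("fixed_weights", {"w_a_fixed": 0.3}),
        ],
    )
    @pytest.mark.parametrize("domain, conflict", [("time", 50.0), ("space", -4.5)])
    def test_binomial_concentration_every_rule(self, rule, kwargs, domain, conflict):
        p = ObserverParams(sigma_v=80.0, sigma_a=60.0, rule=rule, **kwargs)
        spec = TrialSpec(domain, "bimodal", conflict, 20.0)
        prob = response_probability(spec, p)
        n = 40_000
        freq = simulate_responses(spec, p, n, np.random.default_rng(7)).mean()
        assert abs(freq - prob) < 3 * np.sqrt(prob * (1 - prob) / n) + 1e-9

    def test_lapse_floors_and_caps_probability(self):
        p = ObserverParams(sigma_v=1.0, sigma_a=1.0, lapse=0.1)
        far = TrialSpec("time", "visual", 0.0, 1e6)
        assert response_probability(far, p) == pytest.approx(0.95)


class TestSimulateTrial:
    def test_deterministic_given_seed(self):
        spec = TrialSpec("time", "auditory", 0.0, 12.0)
        p = ObserverParams(sigma_v=50.0, sigma_a=50.0, seed=5)
        r1 = [simulate_trial(spec, p, np.random.default_rng(9)).response for _ in range(20)]
        r2 = [simulate_trial(spec, p, np.random.default_rng(9)).response for _ in range(20)]
        assert r1 == r2

    def test_response_is_binary(self, rng):
        spec = TrialSpec("space", "visual", 0.0, 0.0)
        p = ObserverParams(sigma_v=5.0, sigma_a=5.0)
        rec = simulate_trial(spec, p, rng)
        assert rec.response in (0, 1)

    def test_invalid_record_rejected(self):
        spec = TrialSpec("space", "visual", 0.0, 0.0)
        with pytest.raises(ValueError):
            TrialRecord(spec=spec, response=2)


class TestTrainingScreen:
    def test_attentive_observer_passes(self, rng):
        p = ObserverParams(sigma_v=1e-3, sigma_a=1e-3)
        n_correct, passed = simulate_training_screen(p, "space", rng=rng)
        assert passed and n_correct == 10

    def test_zero_threshold_always_passes(self, rng):
        p = ObserverParams(sigma_v=1e6, sigma_a=1e6)
        _, passed = simulate_training_screen(p, "space", pass_threshold=0, rng=rng)
        assert passed

    def test_guesser_pass_rate_matches_binomial_sum(self):
        # P(>=7 of 10 at chance) = sum_{k=7..10} C(10,k) / 2^10
        exact = sum(
            stats.binom.pmf(k, 10, 0.5) for k in range(7, 11)
        )
        assert exact == pytest.approx(0.171875, abs=1e-12)
        gen = np.random.default_rng(11)
        # A huge-σ observer answers at chance even on the "easy" trials.
        p = ObserverParams(sigma_v=1e9, sigma_a=1e9)
        n_rep = 40_000
        hits = sum(
            simulate_training_screen(p, "space", easy_offset=1.0, rng=gen)[1]
            for _ in range(n_rep)
        )
        se = np.sqrt(exact * (1 - exact) / n_rep)
        assert abs(hits / n_rep - exact) < 3 * se

    def test_invalid_thresholds_rejected(self, rng):
        p = ObserverParams(sigma_v=1.0, sigma_a=1.0)
        with pytest.raises(ValueError):
            simulate_training_screen(p, "space", n_trials=5, pass_threshold=7, rng=rng)


class TestSimulateSession:
    def test_time_design_trial_counts(self):
        p = ObserverParams(sigma_v=100.0, sigma_a=80.0, seed=3)
        s = simulate_session(p, TaskDesign.time())
        assert len(s.trials) == 150
        conds = {(t.spec.condition, t.spec.conflict) for t in s.trials}
        assert len(conds) == 5
        counts = {c: 0 for c in conds}
        for t in s.trials:
            counts[(t.spec.condition, t.spec.conflict)] += 1
        assert set(counts.values()) == {30}

    def test_space_design_trial_counts(self):
        p = ObserverParams(sigma_v=6.0, sigma_a=8.0, seed=3)
        s = simulate_session(p, TaskDesign.space())
        assert len(s.trials) == 210
        conds = {(t.spec.condition, t.spec.conflict) for t in s.trials}
        assert len(conds) == 7
        conflicts = {t.spec.conflict for t in s.trials if t.spec.condition == "bimodal"}
        assert conflicts == {-9.0, -4.5, 0.0, 4.5, 9.0}

    def test_same_seed_reproduces_trial_table(self):
        p = ObserverParams(sigma_v=6.0, sigma_a=8.0, seed=21)
        s1 = simulate_session(p, TaskDesign.space())
        s2 = simulate_session(p, TaskDesign.space())
        assert [
            (t.spec.condition, t.spec.conflict, t.spec.probe_offset, t.response)
            for t in s1.trials
        ] == [
            (t.spec.condition, t.spec.conflict, t.spec.probe_offset, t.response)
            for t in s2.trials
        ]

    def test_nonpositive_trial_count_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign.time(trials_per_condition=0)
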