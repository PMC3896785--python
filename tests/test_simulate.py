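"""Steady states, step responses, outcome classification and scores."""

import numpy as np
import pytest

from kinmotif import (
    AdaptationScores,
    OutcomeClass,
    RejectionThresholds,
    StimulusProtocol,
    classify_outcome,
    find_steady_state,
    is_kinetic_solution,
    precision_score,
    sensitivity_score,
    simulate_step_response,
)
from kinmotif.screen import default_range_spec, latin_hypercube_sample
from kinmotif.simulate import StepResponseSummary, _fast_rhs


class TestSteadyState:
    def test_symmetric_equilibrium_found_and_stable(self, nfblb, unit_params):
        state, stable = find_steady_state(nfblb, unit_params, 0.5)
        np.testing.assert_allclose(state, 0.5, atol=1e-8)
        assert stable

    def test_basin_convergence_from_far_guess(self, nfblb, unit_params):
        state, _ = find_steady_state(nfblb, unit_params, 0.5, initial_guess=(0.9, 0.9, 0.9))
        np.testing.assert_allclose(state, 0.5, atol=1e-7)

    def test_root_and_relaxation_agree_on_random_sets(self, nfblb):
        # the two solution paths must land on the same state
        spec = default_range_spec(nfblb, sample_input_edge=False)
        matrix = latin_hypercube_sample(100, spec, seed=99)
        checked = 0
        for _, row in matrix.iterrows():
            params = nfblb.params_from_mapping(row.to_dict())
            try:
                newton_state, stable = find_steady_state(nfblb, params, 0.5)
            except Exception:
                continue
            if not stable:
                continue
            # independent relaxation oracle from a different start
            from scipy.integrate import odeint
            f = _fast_rhs(nfblb, 0.5, params)
            y = odeint(f, [0.4, 0.6, 0.5], np.linspace(0, 2e4, 21),
                       Dfun=lambda s, t: nfblb.jacobian(s, 0.5, params),
                       rtol=1e-10, atol=1e-12, mxstep=100_000)[-1]
            if np.max(np.abs(f(y))) > 1e-9:
                continue   # relaxation not settled within the horizon
            assert np.max(np.abs(y - newton_state)) < 1e-6
            checked += 1
        assert checked >= 60   # enough sets actually compared

    def test_tiny_output_state_still_returned(self, nfblb):
        # vanishing steady states are a classification concern, not an error
        params = dict(zip(nfblb.param_names, np.ones(12)))
        params["K_AC"] = 100.0   # starves the output node
        p = nfblb.params_from_mapping(params)
        state, stable = find_steady_state(nfblb, p, 0.5)
        assert state[-1] < 0.02
        assert stable


class TestStepResponse:
    def test_reference_set_baseline(self, nfblb, unit_params):
        summary = simulate_step_response(nfblb, unit_params)
        assert summary.O1 == pytest.approx(0.5, abs=1e-8)
        assert summary.protocol == StimulusProtocol(0.5, 0.6)
        assert summary.failure is None

    def test_monotone_response_peak_equals_final(self, nfblb):
        # a strongly overdamped set relaxes monotonically: Op == O2
        params = dict(zip(nfblb.param_names, np.ones(12)))
        params["k_BA"] = 0.1   # weak feedback, no overshoot
        p = nfblb.params_from_mapping(params)
        summary = simulate_step_response(nfblb, p)
        assert summary.Op == pytest.approx(summary.O2, rel=1e-3)

    def test_trajectory_stays_in_unit_box(self, nfblb, rng):
        params = 10 ** rng.uniform(-1, 1, 12)
        summary = simulate_step_response(nfblb, params)
        if summary.states.size:
            assert summary.states.min() >= -1e-6
            assert summary.states.max() <= 1 + 1e-6


def _summary_from_curve(times, output, O1=0.5, O2=None, settle=None):
    states = np.column_stack([np.full_like(output, 0.5)] * 2 + [output])
    return StepResponseSummary(
        O1=O1, Op=float(output[np.argmax(np.abs(output - O1))]),
        O2=float(O2 if O2 is not None else output[-1]),
        settle_time=settle, times=times, states=states,
        protocol=StimulusProtocol(), pre_state=np.array([0.5, 0.5, O1]),
    )


class TestOutcomeClassification:
    def test_settled_trajectory_is_ok(self):
        t = np.linspace(0, 100, 500)
        out = 0.5 + 0.1 * np.exp(-t)
        s = _summary_from_curve(t, out, O2=0.5, settle=12.0)
        assert classify_outcome(s) == OutcomeClass.OK

    def test_sustained_sinusoid_is_persistent(self):
        t = np.linspace(0, 1e4, 4000)
        out = 0.5 + 0.05 * np.sin(2 * np.pi * t / 500.0)
        s = _summary_from_curve(t, out, O2=0.5, settle=None)
        assert classify_outcome(s) == OutcomeClass.PERSISTENT_OSCILLATION

    def test_slowly_decaying_ring_is_weakly_damped(self):
        t = np.linspace(0, 1e4, 4000)
        out = 0.5 + 0.05 * np.exp(-t / 4e3) * np.sin(2 * np.pi * t / 500.0)
        s = _summary_from_curve(t, out, O2=0.5, settle=None)
        assert classify_outcome(s) == OutcomeClass.WEAKLY_DAMPED_OSCILLATION

    def test_slow_exponential_is_long_transient(self):
        # time constant T_max/2: settling to 1e-4 of the final value needs
        # ~ ln(0.1/1e-4) * 5e3 ~ 3.5e4 >> T_max
        t = np.linspace(0, 1e4, 2000)
        out = 0.6 - 0.1 * np.exp(-t / 5e3)
        s = _summary_from_curve(t, out, O2=0.6, settle=None)
        assert classify_outcome(s) == OutcomeClass.LONG_TRANSIENT

    def test_vanishing_baseline_is_tiny(self):
        t = np.linspace(0, 100, 200)
        out = np.full_like(t, 1e-4)
        s = _summary_from_curve(t, out, O1=1e-4, O2=1e-4, settle=1.0)
        assert classify_outcome(s) == OutcomeClass.TINY_STEADY_STATE

    def test_boundary_pinned_regulatory_node_is_tiny(self):
        t = np.linspace(0, 100, 200)
        out = 0.5 + 0.01 * np.exp(-t)
        s = _summary_from_curve(t, out, O2=0.5, settle=5.0)
        s.pre_state = np.array([1e-4, 0.5, 0.5])
        assert classify_outcome(s) == OutcomeClass.TINY_STEADY_STATE


class TestScores:
    def test_sensitivity_direct_substitution(self):
        protocol = StimulusProtocol(0.5, 0.6)
        assert sensitivity_score(1.0, 1.4, protocol) == pytest.approx(2.0)
        assert sensitivity_score(1.0, 1.0, protocol) == 0.0

    def test_precision_direct_substitution(self):
        protocol = StimulusProtocol(0.5, 0.6)
        assert precision_score(1.0, 1.02, protocol) == pytest.approx(10.0)
        assert precision_score(1.0, 1.2, protocol) == pytest.approx(1.0)
        assert precision_score(1.0, 1.0, protocol) == np.inf

    def test_scores_are_scale_invariant(self, rng):
        protocol = StimulusProtocol(0.5, 0.6)
        for _ in range(20):
            O1, Op, O2 = rng.uniform(0.05, 0.95, 3)
            c = rng.uniform(0.1, 10.0)
            assert sensitivity_score(c * O1, c * Op, protocol) == pytest.approx(
                sensitivity_score(O1, Op, protocol))
            assert precision_score(c * O1, c * O2, protocol) == pytest.approx(
                precision_score(O1, O2, protocol))

    def test_precision_decreases_with_steady_state_shift(self):
        protocol = StimulusProtocol(0.5, 0.6)
        shifts = np.linspace(0.01, 0.5, 20)
        scores = [precision_score(1.0, 1.0 + s, protocol) for s in shifts]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_score(0.0, 0.5)

    @pytest.mark.parametrize(
        "sens,prec,expected",
        [(1.5, 20.0, True), (1.0, 20.0, False), (1.5, 10.0, False),
         (1.5, np.inf, True), (0.9, np.inf, False)],
    )
    def test_solution_criterion_is_strict(self, sens, prec, expected):
        assert is_kinetic_solution(AdaptationScores(sens, prec)) is expected


class TestProtocolValidation:
    def test_zero_baseline_input_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(I1=0.0, I2=0.6)

    def test_null_step_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(I1=0.5, I2=0.5)
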