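"""Markov model: discretization, transition estimation, simulation, payoffs."""

import math
import warnings
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pji_cea.markov import (
    MarkovCEModel,
    MarkovState,
    StatePayoffs,
    Trajectory,
    TransitionMatrix,
    accumulate_payoffs,
    discretize_to_months,
    estimate_transitions,
    mean_simulated_payoffs,
    simulate_states,
    simulate_trajectory,
)
from pji_cea.records import (
    OperationEvent,
    PatientRecord,
    TreatmentMethod,
    classify_operation,
)

S = MarkovState


def two_stage_record(op_days, censor_days, death_day=None, status="NO_PJI"):
    m = date(2016, 1, 1)
    labels = ["Debridement + spacer installation",
              "Endoprosthesis (EP) installation + spacer removal"]
    ops = tuple(
        OperationEvent(m + timedelta(days=d), classify_operation(l), 100_000.0)
        for d, l in zip(op_days, labels)
    )
    return PatientRecord(
        id="t", birthdate=date(1950, 1, 1), sex="M",
        method=TreatmentMethod.TWO_STAGE_GT2M, manifestation_date=m,
        operations=ops, last_status=status,
        death_date=m + timedelta(days=death_day) if death_day else None,
        censor_date=m + timedelta(days=censor_days),
    )


class TestDiscretize:
    def test_two_stage_worked_chain(self):
        # spacer installed in month 0, second-stage exchange in month 3,
        # observed into month 4: PJI, then three months waiting for the
        # second stage, then observation
        traj = discretize_to_months(two_stage_record([10, 100], 149))
        assert [s for s in traj.states] == [
            S.PJI, S.SECOND_STAGE, S.SECOND_STAGE, S.SECOND_STAGE, S.OBSERVATION
        ]

    def test_last_operation_of_a_month_decides_its_state(self):
        # spacer install and second-stage exchange in the same month: the
        # month reflects the last intervention (the second stage)
        traj = discretize_to_months(two_stage_record([32, 50], 119))
        assert [s for s in traj.states] == [
            S.PJI, S.SECOND_STAGE, S.OBSERVATION, S.OBSERVATION
        ]

    def test_death_months_are_absorbing_tail(self):
        traj = discretize_to_months(
            two_stage_record([10], 179, death_day=95, status="PJI_PRESENT")
        )
        assert [s for s in traj.states] == [
            S.PJI, S.SECOND_STAGE, S.SECOND_STAGE, S.DEATH, S.DEATH, S.DEATH
        ]

    def test_non_pji_operation_month(self):
        m = date(2016, 1, 1)
        ops = (
            OperationEvent(m + timedelta(days=10), classify_operation("Debridement"), 1.0),
            OperationEvent(
                m + timedelta(days=70), classify_operation("Other: (suturing, etc.)"), 1.0
            ),
        )
        r = PatientRecord(
            id="x", birthdate=date(1950, 1, 1), sex="F",
            method=TreatmentMethod.RA, manifestation_date=m, operations=ops,
            last_status="NO_PJI", censor_date=m + timedelta(days=119),
        )
        traj = discretize_to_months(r)
        assert [s for s in traj.states] == [
            S.PJI, S.OBSERVATION, S.NON_PJI_OP, S.OBSERVATION
        ]

    def test_occupancy_conserves_length(self, default_cohort):
        for r in default_cohort[::37]:
            traj = discretize_to_months(r)
            assert sum(traj.occupancy().values()) == len(traj)
            assert traj.states[0] is S.PJI


class TestEstimateTransitions:
    def test_single_trajectory_counts(self):
        traj = Trajectory(states=(S.PJI, S.SECOND_STAGE, S.SECOND_STAGE, S.OBSERVATION))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tm = estimate_transitions([traj])
        assert tm.probabilities[S.PJI, S.SECOND_STAGE] == 1.0
        assert tm.probabilities[S.SECOND_STAGE, S.SECOND_STAGE] == pytest.approx(0.5)
        assert tm.probabilities[S.SECOND_STAGE, S.OBSERVATION] == pytest.approx(0.5)

    def test_unvisited_rows_become_self_loops_with_warning(self):
        traj = Trajectory(states=(S.OBSERVATION,) * 5)
        with pytest.warns(UserWarning, match="self-loop"):
            tm = estimate_transitions([traj])
        assert tm.probabilities[S.PJI, S.PJI] == 1.0
        assert tm.probabilities[S.OBSERVATION, S.OBSERVATION] == 1.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_transitions([])

    def test_death_row_is_absorbing(self):
        traj = Trajectory(states=(S.PJI, S.DEATH, S.DEATH))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tm = estimate_transitions([traj])
        assert tm.probabilities[S.DEATH, S.DEATH] == 1.0

    def test_rows_are_stochastic(self, default_cohort):
        trajs = [discretize_to_months(r, 30) for r in default_cohort]
        tm = estimate_transitions(trajs)
        tm.validate()


RECOVERY_TRUTH = np.array(
    [
        [0.60, 0.25, 0.00, 0.10, 0.05],
        [0.05, 0.65, 0.00, 0.28, 0.02],
        [0.05, 0.00, 0.40, 0.53, 0.02],
        [0.03, 0.00, 0.02, 0.94, 0.01],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ]
)


def recovery_pass(seed, n_traj=500, horizon=30, truth=RECOVERY_TRUTH):
    """Simulate from a known chain, re-estimate, and check every transition
    probability against a simultaneous 95% confidence set (exact
    Clopper-Pearson intervals, Bonferroni-corrected over the free entries)."""
    states = simulate_states(truth, n_traj, horizon, seed)
    trajs = [Trajectory(states=tuple(S(int(x)) for x in row)) for row in states]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = estimate_transitions(trajs)
    n_free = int((truth[: S.DEATH] > 0).sum())
    a = 0.05 / n_free
    for i in range(S.DEATH):  # DEATH row is forced absorbing
        n = est.counts[i].sum()
        if n == 0:
            continue
        for j in range(len(S)):
            x = est.counts[i, j]
            lo = stats.beta.ppf(a / 2, x, n - x + 1) if x > 0 else 0.0
            hi = stats.beta.ppf(1 - a / 2, x + 1, n - x) if x < n else 1.0
            if not lo <= truth[i, j] <= hi:
                return False
    return True


def test_parameter_recovery_standing_check():
    assert recovery_pass(seed=0)


class TestSimulate:
    def test_pji_self_loop_keeps_all_pji(self):
        p = np.eye(5)
        traj = simulate_trajectory(p, 12, 0)
        assert set(traj.states) == {S.PJI}

    def test_certain_death_transition_is_absorbing(self):
        p = np.eye(5)
        p[S.PJI] = [0, 0, 0, 0, 1]
        traj = simulate_trajectory(p, 6, 0)
        assert [s for s in traj.states] == [S.PJI] + [S.DEATH] * 5

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            simulate_states(np.ones((5, 5)), 10, 5, 0)

    def test_next_state_frequencies_match_row(self):
        p = np.tile([0.2, 0.3, 0.1, 0.35, 0.05], (5, 1))
        p[S.DEATH] = [0, 0, 0, 0, 1]
        # resample the PJI row 100,000 times via two-month trajectories
        states = simulate_states(p, 100_000, 2, 11)
        freq = np.bincount(states[:, 1], minlength=5) / states.shape[0]
        for j in range(5):
            se = math.sqrt(p[0, j] * (1 - p[0, j]) / states.shape[0])
            assert abs(freq[j] - p[0, j]) < 3 * se


class TestPayoffs:
    def test_worked_five_month_chain(self):
        traj = Trajectory(
            states=(S.PJI, S.SECOND_STAGE, S.SECOND_STAGE, S.SECOND_STAGE, S.OBSERVATION)
        )
        qaly, cost = accumulate_payoffs(traj, StatePayoffs(), annualize=False)
        assert qaly == pytest.approx(1 * 0.35 + 3 * 0.7 + 1 * 0.85)  # 3.30
        # five cost terms: PJI month + PJI surgery + 3 spacer months +
        # second-stage surgery + observation month
        p = StatePayoffs()
        expected_cost = (
            p.monthly_cost_per_state[S.PJI]
            + p.operation_cost_per_transition[(S.PJI, S.SECOND_STAGE)]
            + 3 * p.monthly_cost_per_state[S.SECOND_STAGE]
            + p.operation_cost_per_transition[(S.SECOND_STAGE, S.OBSERVATION)]
            + p.monthly_cost_per_state[S.OBSERVATION]
        )
        assert cost == pytest.approx(expected_cost)

    def test_annualized_worked_chain(self):
        traj = Trajectory(
            states=(S.PJI, S.SECOND_STAGE, S.SECOND_STAGE, S.SECOND_STAGE, S.OBSERVATION)
        )
        qaly, _ = accumulate_payoffs(traj, StatePayoffs(), annualize=True)
        assert qaly == pytest.approx(3.30 / 12)

    def test_all_death_trajectory_accrues_nothing(self):
        traj = Trajectory(states=(S.DEATH,) * 6)
        assert accumulate_payoffs(traj, StatePayoffs()) == (0.0, 0.0)

    def test_death_utility_must_be_zero(self):
        with pytest.raises(ValueError, match="DEATH"):
            StatePayoffs(utility_per_state={**StatePayoffs().utility_per_state, S.DEATH: 0.1})

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.lists(st.sampled_from(list(S)), min_size=1, max_size=8),
        b=st.lists(st.sampled_from(list(S)), min_size=1, max_size=8),
    )
    def test_payoff_linearity_over_concatenation(self, a, b):
        p = StatePayoffs()
        qa, ca = accumulate_payoffs(Trajectory(states=tuple(a)), p)
        qb, cb = accumulate_payoffs(Trajectory(states=tuple(b)), p)
        qab, cab = accumulate_payoffs(Trajectory(states=tuple(a + b)), p)
        junction = p.operation_cost_per_transition.get((a[-1], b[0]), 0.0)
        if a[-1] == b[0]:
            junction = 0.0
        assert qab == pytest.approx(qa + qb)
        assert cab == pytest.approx(ca + cb + junction)


class TestMarkovCEModel:
    def test_fit_and_analytic_expectation(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MarkovCEModel(method=TreatmentMethod.TWO_STAGE_GT2M).fit(default_cohort)
        qaly, cost = model.expected_payoffs()
        assert 0 < qaly < 30 / 12  # bounded by perfect health over the horizon
        assert cost > 0

    def test_analytic_equals_monte_carlo_mean(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MarkovCEModel(method=TreatmentMethod.RA).fit(default_cohort)
        qaly, cost = model.expected_payoffs()
        states = model.simulate(10_000, rng=3)
        mq, mc, se_q, se_c = mean_simulated_payoffs(states, model.payoffs_)
        assert abs(mq - qaly) < 3 * se_q
        assert abs(mc - cost) < 3 * se_c

    def test_bootstrap_transition_intervals_bracket_estimates(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MarkovCEModel(
                method=TreatmentMethod.ONE_STAGE, bootstrap=True, random_state=2
            ).fit(default_cohort)
        tm = model.transition_matrix_
        assert tm.lower is not None
        assert (tm.lower <= tm.upper + 1e-12).all()
        assert (tm.lower >= 0).all() and (tm.upper <= 1).all()

    def test_no_records_for_method_is_an_error(self):
        with pytest.raises(ValueError, match="RA"):
            MarkovCEModel(method=TreatmentMethod.RA).fit([])
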