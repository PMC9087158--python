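"""Treatment health dynamics, wage accrual and return-to-work pathways."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from worksim import (
    Employer,
    PolicyLevers,
    RtwOutcome,
    SimulationConfig,
    accrue_wage_cost,
    apply_occ_rehab,
    attempt_employer_rtw,
    check_termination,
    make_worker,
    readiness_with_advertising,
    rtw_gate,
    run_simulation,
    treat_step,
)
from worksim.population import Ledger


def _noiseless(**kwargs):
    return PolicyLevers(treatment_noise_amplitude=0.0, **kwargs)


class TestTreatStep:
    def test_five_percent_of_gap(self, rng):
        w = make_worker({"health": 0.0, "responsiveness": 1.0,
                         "stage": "treatment"})
        treat_step(w, _noiseless(), rng)
        assert w.health == pytest.approx(5.0, abs=1e-12)

    def test_zero_gap_is_fixed_point(self, rng):
        w = make_worker({"health": 100.0, "responsiveness": 1.0,
                         "stage": "treatment"})
        treat_step(w, _noiseless(), rng)
        assert w.health == 100.0

    def test_responsiveness_scales_gain(self, rng):
        w = make_worker({"health": 50.0, "responsiveness": 0.8,
                         "stage": "treatment"})
        treat_step(w, _noiseless(), rng)
        assert w.health == pytest.approx(52.0, abs=1e-12)

    def test_noiseless_trajectory_matches_closed_form(self, rng):
        levers = _noiseless()
        for r in (1.0, 0.6, -0.5):
            w = make_worker({"health": 20.0, "responsiveness": r,
                             "stage": "treatment"})
            for t in range(1, 41):
                treat_step(w, levers, rng)
                expected = 100.0 - 80.0 * (1.0 - 0.05 * r) ** t
                assert abs(w.health - max(0.0, min(expected, 100.0))) < 1e-9

    def test_noisy_mean_converges_to_curve(self, levers):
        """Monte-Carlo mean with noise matches 100 - 100*(0.95)^t."""
        rng = np.random.default_rng(4)
        n, t_max = 10_000, 20
        healths = np.zeros(n)
        workers = [
            make_worker({"id": i, "health": 0.0, "responsiveness": 1.0,
                         "stage": "treatment"})
            for i in range(n)
        ]
        for t in range(1, t_max + 1):
            for i, w in enumerate(workers):
                treat_step(w, levers, rng)
        final = np.array([w.health for w in workers])
        expected = 100.0 - 100.0 * 0.95**t_max
        se = final.std(ddof=1) / math.sqrt(n)
        assert abs(final.mean() - expected) < 3 * se + 1e-9

    def test_cost_recorded_on_worker_and_system(self, levers, rng):
        w = make_worker({"stage": "treatment"})
        system = Ledger()
        treat_step(w, levers, rng, system)
        assert w.ledger.get_cents("treatment") > 0
        assert system.get_cents("treatment") == w.ledger.get_cents("treatment")


class TestTreatmentDenial:
    def test_zero_rate_never_denies(self):
        from worksim import maybe_deny_treatment

        levers = PolicyLevers(treatment_denial_rate=0.0)
        rng = np.random.default_rng(0)
        w = make_worker({"stage": "treatment"})
        assert not any(maybe_deny_treatment(w, levers, rng) for _ in range(500))

    def test_always_denied_mean_health_change_is_noise_only(self):
        from worksim.treatment import denied_health_update

        levers = PolicyLevers()
        rng = np.random.default_rng(2)
        changes = []
        for _ in range(10_000):
            w = make_worker({"health": 50.0, "stage": "treatment"})
            denied_health_update(w, levers, rng)
            changes.append(w.health - 50.0)
        changes = np.array(changes)
        # eps is uniform on [-1, 1]: mean 0, so the average change ~ 0
        assert abs(changes.mean()) < 3 * changes.std(ddof=1) / 100.0
        assert abs(changes).max() <= 1.0

    def test_denial_event_lowers_trust_in_full_run(self):
        levers = PolicyLevers(treatment_denial_rate=1.0, arrival_rate=5)
        series, state = run_simulation(
            SimulationConfig(n_steps=60, seed=3, levers=levers)
        )
        treated = [
            w for w in list(state.workers.values()) + state.exited
            if w.accepted == "accepted"
        ]
        assert treated
        # every treatment step was denied: accepted workers lost trust
        assert any(
            any(tag == "treatment_denied" for _, tag in w.memory)
            for w in treated
        )


class TestWageCost:
    def test_full_incapacity(self, levers):
        w = make_worker({"salary": 55_000.0})
        cost = accrue_wage_cost(w, levers, fitness_credit=0.0)
        assert cost == pytest.approx(0.80 * 55_000 / 50)

    def test_partial_fitness_reduces_prorata(self, levers):
        w = make_worker({"salary": 55_000.0})
        cost = accrue_wage_cost(w, levers, fitness_credit=0.75)
        assert cost == pytest.approx(0.25 * 0.80 * 55_000 / 50)

    def test_fully_fit_costs_nothing(self, levers):
        w = make_worker({})
        assert accrue_wage_cost(w, levers, fitness_credit=1.0) == 0.0

    def test_partial_strictly_cheaper_than_full(self, levers):
        w = make_worker({})
        full = accrue_wage_cost(w, levers, fitness_credit=0.0)
        partial = accrue_wage_cost(w, levers, fitness_credit=0.4)
        assert 0 < partial < full

    def test_invalid_credit_rejected(self, levers):
        w = make_worker({})
        with pytest.raises(ValueError, match="fitness_credit"):
            accrue_wage_cost(w, levers, fitness_credit=1.5)


class TestRtwGate:
    @pytest.mark.parametrize("policy,health,expected", [
        ("neutral", 96.0, "to_rtw_pool"),
        ("neutral", 80.0, "stay_in_treatment"),
        ("discourage", 80.0, "stay_in_treatment"),
        ("encourage", 96.0, "to_rtw_pool"),
        ("encourage", 80.0, "to_employer_attempt"),
        ("encourage", 60.0, "stay_in_treatment"),
    ])
    def test_gate_truth_table(self, policy, health, expected):
        levers = PolicyLevers(rtw_policy=policy, early_rtw_health_floor=70.0)
        w = make_worker({"health": health, "stage": "treatment"})
        assert rtw_gate(w, levers) == expected


class TestEmployerAttempt:
    def test_ready_employer_partial_rtw(self, levers):
        w = make_worker({"health": 80.0})
        outcome, used = attempt_employer_rtw(w, Employer(20.0), levers)
        assert outcome is RtwOutcome.PARTIAL_RTW and used == 0

    def test_unready_employer_failed_rtw(self, levers):
        w = make_worker({"health": 80.0})
        outcome, used = attempt_employer_rtw(w, Employer(5.0), levers)
        assert outcome is RtwOutcome.FAILED_RTW
        assert w.failed_rtw_count == 1

    def test_occ_rehab_bridges_and_charges_once(self):
        levers = PolicyLevers(occ_rehab_enabled=True)
        system = Ledger()
        w = make_worker({"health": 80.0})
        outcome, used = attempt_employer_rtw(
            w, Employer(5.0), levers, occ_rehab_slots=1, system_ledger=system
        )
        assert outcome is RtwOutcome.PARTIAL_RTW and used == 1
        assert system.get("occ_rehab") == 10_000.0
        # a second supported attempt for the same worker is not re-charged
        apply_occ_rehab(w, Employer(0.0), levers, system)
        assert system.get("occ_rehab") == 10_000.0

    def test_occ_rehab_capacity_bound(self):
        levers = PolicyLevers(occ_rehab_enabled=True)
        slots = 1
        outcomes = []
        for i in range(2):
            w = make_worker({"id": i, "health": 80.0})
            outcome, used = attempt_employer_rtw(
                w, Employer(0.0), levers, occ_rehab_slots=slots
            )
            slots -= used
            outcomes.append(outcome)
        assert outcomes == [RtwOutcome.PARTIAL_RTW, RtwOutcome.FAILED_RTW]

    def test_occ_rehab_never_increases_failed_rtw(self):
        """Paired 400-step runs: enabling occ-rehab cannot add failures."""
        base = PolicyLevers(rtw_policy="encourage")
        final_off, _ = _final(base, seed=21)
        final_on, _ = _final(
            dataclasses.replace(base, occ_rehab_enabled=True), seed=21
        )
        assert final_on.n_failed_rtw <= final_off.n_failed_rtw
        assert final_on.n_partial_rtw >= final_off.n_partial_rtw


def _final(levers, seed, n_steps=400):
    series, state = run_simulation(
        SimulationConfig(n_steps=n_steps, seed=seed, levers=levers)
    )
    return series[-1], state


class TestAdvertising:
    def test_no_spend_identity(self):
        levers = PolicyLevers(advertising_spend=0.0)
        assert readiness_with_advertising(30.0, levers) == 30.0

    def test_monotone_in_spend(self):
        readies = [
            readiness_with_advertising(
                30.0, PolicyLevers(advertising_spend=s)
            )
            for s in (0.0, 10.0, 100.0, 1000.0, 10_000.0)
        ]
        assert readies == sorted(readies)

    def test_saturates_below_cap(self):
        levers = PolicyLevers(advertising_spend=1e12)
        assert readiness_with_advertising(80.0, levers) <= 100.0


class TestTermination:
    def test_boundary_is_strict(self):
        levers = PolicyLevers(max_claim_duration=100)
        w = make_worker({"claim_active_since": 0, "accepted": "accepted"})
        assert not check_termination(w, levers, t=100)
        assert check_termination(w, levers, t=101)

    def test_infinite_limit_never_terminates(self):
        levers = PolicyLevers(max_claim_duration=math.inf)
        w = make_worker({"claim_active_since": 0, "accepted": "accepted"})
        assert not check_termination(w, levers, t=10**9)
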