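"""Cohort engine: tunnel expansion, matrices, trace dynamics, payoffs."""

import dataclasses

import numpy as np
import pytest

from glottic_cea import (
    DEAD,
    CostSchedule,
    ModelConfig,
    ResidualRule,
    TimeIndexedValue,
    TransitionSpec,
    accumulate,
    build_matrix,
    expand_tunnels,
    run_cohort,
    run_model,
    validate,
)
from glottic_cea.engine import InfeasibleRowError, discount_weights
from glottic_cea.params import MODEL_TIME, TIME_IN_STATE, with_parameter_values

ANNUITY_15Y_5PCT = 10.898641  # sum of 1.05^-(t-1), t = 1..15


def single_state_model(
    *, utility=1.0, death=0.0, rate=0.0, cycles=15, cost=0.0, **toggles
) -> ModelConfig:
    """Minimal one-transient-state model for closed-form checks."""
    transitions = []
    if death:
        transitions.append(
            TransitionSpec("alive", DEAD, TimeIndexedValue((death,)), MODEL_TIME)
        )
    return validate(
        ModelConfig(
            strategy="toy",
            perspective="toy",
            states=("alive", DEAD),
            transitions=transitions,
            residual_rules=[ResidualRule("alive", "alive")],
            cost_schedules={
                "alive": CostSchedule("alive", TimeIndexedValue((cost,)), MODEL_TIME)
            },
            utilities={"alive": utility, DEAD: 0.0},
            discount_rate=rate,
            horizon_cycles=cycles,
            start_distribution={"alive": 1.0},
            **toggles,
        )
    )


class TestExpansion:
    def test_fixture_expands_to_twelve_states(self, hypofrt_public):
        space = expand_tunnels(hypofrt_public)
        assert space.size == 12
        labels = space.labels()
        assert labels[0] == "controlled_disease"
        assert labels[-1] == DEAD
        assert "local_failure_1" in labels and "local_failure_5" in labels
        assert "distant_failure_5" in labels

    def test_model_time_only_model_stays_unexpanded(self):
        cfg = single_state_model(death=0.1)
        space = expand_tunnels(cfg)
        assert space.size == 2
        assert space.labels() == ["alive", DEAD]

    def test_k1_tunnel_equivalent_to_untunnelled(self):
        """A one-year time-in-state vector behaves exactly like model_time."""
        base = single_state_model(death=0.07, rate=0.05, cost=100.0)
        tunnelled = dataclasses.replace(
            base,
            transitions=[
                TransitionSpec("alive", DEAD, TimeIndexedValue((0.07,)),
                               TIME_IN_STATE)
            ],
            cost_schedules={
                "alive": CostSchedule("alive", TimeIndexedValue((100.0,)),
                                      TIME_IN_STATE)
            },
        )
        a, b = run_model(base), run_model(validate(tunnelled))
        assert a.total_cost == pytest.approx(b.total_cost, abs=1e-12)
        assert a.total_qaly == pytest.approx(b.total_qaly, abs=1e-12)


class TestBuildMatrix:
    def test_cfrt_controlled_row_cycle1(self, cfrt_public):
        space = expand_tunnels(cfrt_public)
        m = build_matrix(cfrt_public, space, 1)
        cd = space.index[("controlled_disease", None)]
        row = {
            label: m[cd, j]
            for j, label in enumerate(space.labels())
            if m[cd, j] > 0
        }
        assert row == {
            "controlled_disease": pytest.approx(0.94),
            "local_failure_1": pytest.approx(0.03),
            DEAD: pytest.approx(0.03),
        }

    def test_distant_failure_tail_row(self, public_pair):
        for cfg in public_pair:
            space = expand_tunnels(cfg)
            m = build_matrix(cfg, space, 1)
            i = space.index[("distant_failure", 5)]
            assert m[i, i] == pytest.approx(0.01)
            assert m[i, space.entry_index[DEAD]] == pytest.approx(0.99)

    def test_dead_row_is_identity(self, hypofrt_public):
        space = expand_tunnels(hypofrt_public)
        for cycle in (1, 7, 15):
            m = build_matrix(hypofrt_public, space, cycle)
            row = m[space.entry_index[DEAD]]
            expected = np.zeros(space.size)
            expected[space.entry_index[DEAD]] = 1.0
            np.testing.assert_array_equal(row, expected)

    def test_tunnel_advance_routing(self, hypofrt_public):
        space = expand_tunnels(hypofrt_public)
        m = build_matrix(hypofrt_public, space, 1)
        lf2 = space.index[("local_failure", 2)]
        lf3 = space.index[("local_failure", 3)]
        # stay mass of tunnel year 2 moves to tunnel year 3
        assert m[lf2, lf3] == pytest.approx(1 - 0.017 - 0.049)

    def test_rows_stochastic(self, all_fixtures):
        for cfg in all_fixtures:
            space = expand_tunnels(cfg)
            for cycle in range(1, cfg.horizon_cycles + 1):
                m = build_matrix(cfg, space, cycle)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert (m >= 0).all() and (m <= 1).all()

    def test_infeasible_row_names_state_and_cycle(self, hypofrt_public):
        bad = with_parameter_values(
            hypofrt_public, "prob:local_failure->dead", (0.5, 0.99, 0.5, 0.5, 0.5)
        )
        space = expand_tunnels(bad)
        with pytest.raises(InfeasibleRowError, match="local_failure.*cycle 3"):
            build_matrix(bad, space, 3)


class TestCohortTrace:
    def test_single_state_conservation(self):
        cfg = single_state_model()
        trace = run_cohort(cfg)
        np.testing.assert_allclose(
            trace.occupancy[:, 0], np.ones(cfg.horizon_cycles + 1)
        )

    def test_first_cycle_mortality(self, hypofrt_public):
        trace = run_cohort(hypofrt_public)
        assert trace.dead_fraction()[1] == pytest.approx(0.03)

    def test_row_sums_and_dead_monotonicity(self, all_fixtures):
        for cfg in all_fixtures:
            trace = run_cohort(cfg)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.dead_fraction()
            assert (np.diff(dead) >= -1e-15).all()


class TestAccumulate:
    def test_undiscounted_annuity(self):
        totals = run_model(single_state_model(rate=0.0))
        assert totals.total_qaly == pytest.approx(15.0)
        assert totals.total_lyg == pytest.approx(15.0)

    def test_discounted_annuity(self):
        totals = run_model(single_state_model(rate=0.05))
        assert totals.total_lyg == pytest.approx(ANNUITY_15Y_5PCT, abs=1e-6)

    def test_discount_first_cycle_divides_by_one_plus_r(self):
        a = run_model(single_state_model(rate=0.05))
        b = run_model(single_state_model(rate=0.05, discount_first_cycle=True))
        assert b.total_lyg == pytest.approx(a.total_lyg / 1.05)

    def test_discount_limit_recovers_undiscounted_sums(self, hypofrt_public):
        undiscounted = dataclasses.replace(hypofrt_public.copy(), discount_rate=0.0)
        limit = dataclasses.replace(hypofrt_public.copy(), discount_rate=1e-12)
        a, b = run_model(undiscounted), run_model(limit)
        assert b.total_cost == pytest.approx(a.total_cost, rel=1e-9)
        assert b.total_qaly == pytest.approx(a.total_qaly, rel=1e-9)
        assert b.total_lyg == pytest.approx(a.total_lyg, rel=1e-9)

    def test_initial_cost_not_discounted(self):
        paid = run_model(single_state_model(rate=0.05, cost=0.0))
        cfg = single_state_model(rate=0.05, cost=0.0)
        cfg.initial_one_time_cost = 1_000.0
        with_initial = run_model(cfg)
        assert with_initial.total_cost - paid.total_cost == pytest.approx(1_000.0)

    def test_half_cycle_correction_averages_occupancy(self):
        cfg = single_state_model(death=0.2, rate=0.0, cycles=1)
        plain = run_model(cfg)
        hc_cfg = single_state_model(death=0.2, rate=0.0, cycles=1,
                                    half_cycle_correction=True)
        corrected = run_model(hc_cfg)
        assert plain.total_lyg == pytest.approx(1.0)
        assert corrected.total_lyg == pytest.approx(0.9)  # (1 + 0.8) / 2

    def test_qaly_never_exceeds_lyg(self, all_fixtures):
        for cfg in all_fixtures:
            totals = run_model(cfg)
            assert totals.total_qaly <= totals.total_lyg
            assert totals.total_cost >= 0

    def test_mortality_monotonicity(self, cfrt_public):
        """Uniformly lowering the stay probability weakly lowers QALY and LYG."""
        base = run_model(cfrt_public)
        worse_cfg = with_parameter_values(
            cfrt_public,
            "prob:controlled_disease->controlled_disease",
            tuple(max(p - 0.05, 0.0) for p in (0.94, 0.90, 0.85, 0.81, 0.77)),
        )
        worse = run_model(worse_cfg)
        # stay mass shifts into local failure, which is deadlier than CD
        assert worse.total_qaly <= base.total_qaly
        assert worse.total_lyg <= base.total_lyg

    def test_per_cycle_breakdown_sums_to_totals(self, hypofrt_public):
        totals = run_model(hypofrt_public)
        pc = totals.per_cycle
        assert pc["cost"].sum() + hypofrt_public.initial_one_time_cost == \
            pytest.approx(totals.total_cost)
        assert pc["qaly"].sum() == pytest.approx(totals.total_qaly)
        assert len(pc) == hypofrt_public.horizon_cycles


def test_discount_weights_convention():
    cfg = single_state_model(rate=0.05)
    w = discount_weights(cfg)
    assert w[0] == 1.0
    assert w[1] == pytest.approx(1 / 1.05)
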