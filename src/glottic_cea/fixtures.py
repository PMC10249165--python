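"""Canonical model inputs for the early-stage glottic cancer case study.

Four model instances are provided: two radiotherapy strategies (HYPOFRT,
2.25 Gy/fraction hypofractionation; CFRT, 2 Gy/fraction conventional
fractionation) under two Brazilian payer perspectives (public SUS
reimbursement, private CBHPM reimbursement).

Structure: a 65-year-old male cohort starts in ``controlled_disease``.  Each
cycle (1 year) a patient either stays controlled, dies of background causes
(0.03/year), or develops a local failure (the residual mass), which is
salvaged by total laryngectomy.  From ``local_failure`` a patient may
progress to ``distant_failure`` or die, with probabilities that depend on
time since the failure (tunnel states, 5 years tabulated, constant
afterwards); otherwise they remain in the salvaged state.  From
``distant_failure`` the only exit is death.  Costs are yearly per state;
local/distant failure costs are clocked by time-in-state so that the
expensive first year (salvage surgery, chemotherapy) is paid on entry
regardless of the calendar year; controlled-disease costs follow model time
(the state is never re-entered, so the clocks coincide).

The two strategies differ only in the probability of remaining controlled
and share every other input, including the one-time radiotherapy
reimbursement (fixed per procedure in both Brazilian systems, independent of
the number of fractions).
"""

from __future__ import annotations

from .params import (
    DEAD,
    MODEL_TIME,
    TIME_IN_STATE,
    CostSchedule,
    DistributionSpec,
    ModelConfig,
    ResidualRule,
    TimeIndexedValue,
    TransitionSpec,
    validate,
)

CONTROLLED = "controlled_disease"
LOCAL_FAILURE = "local_failure"
DISTANT_FAILURE = "distant_failure"

STRATEGIES = ("HYPOFRT", "CFRT")
PERSPECTIVES = ("public", "private")

# probability of staying in controlled disease, years 1..5 (constant after)
STAY_CONTROLLED = {
    "HYPOFRT": (0.97, 0.96, 0.94, 0.94, 0.93),
    "CFRT": (0.94, 0.90, 0.85, 0.81, 0.77),
}
STAY_SD = {"HYPOFRT": 0.014, "CFRT": 0.07}

P_CONTROLLED_DEATH = 0.03  # background mortality, controlled disease only
P_CONTROLLED_DEATH_SD = 0.014

P_LF_TO_DF = (0.008, 0.017, 0.026, 0.034, 0.043)  # by time since failure
P_LF_TO_DF_SD = 0.013
P_LF_DEATH = (0.025, 0.049, 0.073, 0.09, 0.12)
P_LF_DEATH_SD = 0.037
P_DF_DEATH = (0.601893, 0.84, 0.93, 0.97, 0.99)
P_DF_DEATH_SD = 0.14

UTILITIES = {CONTROLLED: 0.85, LOCAL_FAILURE: 0.57, DISTANT_FAILURE: 0.42}
UTILITY_SD = {CONTROLLED: 0.017, LOCAL_FAILURE: 0.060, DISTANT_FAILURE: 0.006}

INITIAL_COST = {"public": 4_168.00, "private": 37_396.24}
INITIAL_COST_SD = {"public": 1_667.2, "private": 14_958.49}

YEARLY_COSTS = {
    "public": {
        CONTROLLED: (823.92, 707.16, 220.41, 220.41, 220.41),
        LOCAL_FAILURE: (1_804.23, 707.16, 220.41, 220.41, 220.41),
        DISTANT_FAILURE: (5_400.76, 484.00, 220.41, 220.41, 220.41),
    },
    "private": {
        CONTROLLED: (14_611.79, 13_919.07, 2_897.68, 2_897.68, 2_897.68),
        LOCAL_FAILURE: (20_838.67, 13_919.07, 2_897.68, 2_897.68, 2_897.68),
        DISTANT_FAILURE: (24_211.79, 13_919.07, 2_897.68, 2_897.68, 2_897.68),
    },
}
YEARLY_COST_SD = {
    "public": {CONTROLLED: 301.42, LOCAL_FAILURE: 687.01, DISTANT_FAILURE: 2_371.48},
    "private": {
        CONTROLLED: 6_231.18,
        LOCAL_FAILURE: 8_300.39,
        DISTANT_FAILURE: 9_573.99,
    },
}

WTP_QALY = 40_000.0  # Brazilian cost-effectiveness threshold, R$/QALY
WTP_LYG = 35_000.0   # R$/LYG

DISCOUNT_RATE = 0.05
HORIZON_CYCLES = 15

# printed USD equivalents (CCEMG/PPP web conversion, year 2022) — static
# metadata only, never recomputed
USD_ANNOTATIONS = {
    "wtp_qaly_usd": 18_107.74,
    "wtp_lyg_usd": 15_844.27,
    "wtp_public_ceac_usd": 905.39,
    "wtp_private_ceac_usd": 7_243.10,
}


def _mean(v) -> float:
    return sum(v) / len(v)


def table1_fixture(strategy: str, perspective: str) -> ModelConfig:
    """Build the canonical model instance for a strategy and payer perspective."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if perspective not in PERSPECTIVES:
        raise ValueError(
            f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}"
        )

    states = (CONTROLLED, LOCAL_FAILURE, DISTANT_FAILURE, DEAD)
    transitions = [
        TransitionSpec(
            CONTROLLED, CONTROLLED,
            TimeIndexedValue(STAY_CONTROLLED[strategy]), MODEL_TIME,
        ),
        TransitionSpec(
            CONTROLLED, DEAD, TimeIndexedValue((P_CONTROLLED_DEATH,)), MODEL_TIME
        ),
        TransitionSpec(
            LOCAL_FAILURE, DISTANT_FAILURE,
            TimeIndexedValue(P_LF_TO_DF), TIME_IN_STATE,
        ),
        TransitionSpec(
            LOCAL_FAILURE, DEAD, TimeIndexedValue(P_LF_DEATH), TIME_IN_STATE
        ),
        TransitionSpec(
            DISTANT_FAILURE, DEAD, TimeIndexedValue(P_DF_DEATH), TIME_IN_STATE
        ),
    ]
    residual_rules = [
        ResidualRule(CONTROLLED, LOCAL_FAILURE),   # failures are the residual
        ResidualRule(LOCAL_FAILURE, LOCAL_FAILURE),  # stay (tunnel advance)
        ResidualRule(DISTANT_FAILURE, DISTANT_FAILURE),
    ]
    costs = {
        CONTROLLED: CostSchedule(
            CONTROLLED, TimeIndexedValue(YEARLY_COSTS[perspective][CONTROLLED]),
            MODEL_TIME,
        ),
        LOCAL_FAILURE: CostSchedule(
            LOCAL_FAILURE, TimeIndexedValue(YEARLY_COSTS[perspective][LOCAL_FAILURE]),
            TIME_IN_STATE,
        ),
        DISTANT_FAILURE: CostSchedule(
            DISTANT_FAILURE,
            TimeIndexedValue(YEARLY_COSTS[perspective][DISTANT_FAILURE]),
            TIME_IN_STATE,
        ),
    }

    psa = {
        f"prob:{CONTROLLED}->{CONTROLLED}": DistributionSpec(
            "beta", _mean(STAY_CONTROLLED[strategy]), STAY_SD[strategy]
        ),
        f"prob:{CONTROLLED}->{DEAD}": DistributionSpec(
            "beta", P_CONTROLLED_DEATH, P_CONTROLLED_DEATH_SD
        ),
        f"prob:{LOCAL_FAILURE}->{DISTANT_FAILURE}": DistributionSpec(
            "beta", _mean(P_LF_TO_DF), P_LF_TO_DF_SD
        ),
        f"prob:{LOCAL_FAILURE}->{DEAD}": DistributionSpec(
            "beta", _mean(P_LF_DEATH), P_LF_DEATH_SD
        ),
        f"prob:{DISTANT_FAILURE}->{DEAD}": DistributionSpec(
            "beta", _mean(P_DF_DEATH), P_DF_DEATH_SD
        ),
        "initial_cost": DistributionSpec(
            "gamma", INITIAL_COST[perspective], INITIAL_COST_SD[perspective]
        ),
    }
    for s in (CONTROLLED, LOCAL_FAILURE, DISTANT_FAILURE):
        psa[f"utility:{s}"] = DistributionSpec("beta", UTILITIES[s], UTILITY_SD[s])
        psa[f"cost:{s}"] = DistributionSpec(
            "gamma",
            _mean(YEARLY_COSTS[perspective][s]),
            YEARLY_COST_SD[perspective][s],
        )

    config = ModelConfig(
        strategy=strategy,
        perspective=perspective,
        states=states,
        transitions=transitions,
        residual_rules=residual_rules,
        cost_schedules=costs,
        utilities={**UTILITIES, DEAD: 0.0},
        initial_one_time_cost=INITIAL_COST[perspective],
        discount_rate=DISCOUNT_RATE,
        horizon_cycles=HORIZON_CYCLES,
        cycle_length_years=1.0,
        start_distribution={CONTROLLED: 1.0},
        wtp_qaly=WTP_QALY,
        wtp_lyg=WTP_LYG,
        psa_specs=psa,
    )
    return validate(config)


def fixture_pair(perspective: str) -> tuple[ModelConfig, ModelConfig]:
    """(HYPOFRT, CFRT) pair for one perspective."""
    return table1_fixture("HYPOFRT", perspective), table1_fixture("CFRT", perspective)
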