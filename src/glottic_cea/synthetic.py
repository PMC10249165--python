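"""Synthetic model generation and an individual-level microsimulation oracle.

``generate_random_model`` draws random but always-valid model configurations
(row-stochastic time-indexed transitions via Dirichlet allocation, positive
gamma-scale costs, utilities in [0,1], a single absorbing dead state) so
every pipeline stage can be property-tested without external data.

``microsimulate`` is an independent check on the cohort engine: it simulates
individual patient trajectories through the same expanded state space using
the same per-cycle matrices and payoff rules, and aggregates per-patient
discounted cost/QALY/life-years.  By the law of large numbers its means
converge on the cohort model's expectations; it deliberately shares only the
matrix-builder and payoff contracts, not the trace code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import (
    ExpandedStateSpace,
    build_matrix,
    discount_weights,
    expand_tunnels,
    payoff_arrays,
)
from .params import (
    DEAD,
    MODEL_TIME,
    TIME_IN_STATE,
    CostSchedule,
    ModelConfig,
    ResidualRule,
    TimeIndexedValue,
    TransitionSpec,
    validate,
)


@dataclass(frozen=True)
class RandomModelSpec:
    """Envelope of the random model generator."""

    n_transient_states: int = 3      # 2..5
    tunnel_length: int = 3           # 1..6 tabulated years
    seed: int = 0
    cost_scale: float = 1_000.0
    utility_low: float = 0.2
    utility_high: float = 1.0
    horizon_cycles: int = 12
    discount_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (2 <= self.n_transient_states <= 5):
            raise ValueError("n_transient_states must be in 2..5")
        if not (1 <= self.tunnel_length <= 6):
            raise ValueError("tunnel_length must be in 1..6")


def generate_random_model(spec: RandomModelSpec) -> ModelConfig:
    """Random valid ModelConfig, deterministic under the spec's seed.

    State i may move to any later state or death (a progressive topology, so
    the residual "stay" mass is always feasible); transition rows are drawn
    from a Dirichlet over (stay, targets..., death) independently per year.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.tunnel_length
    names = [f"state_{i}" for i in range(spec.n_transient_states)]
    states = tuple(names) + (DEAD,)

    transitions: list[TransitionSpec] = []
    residual_rules: list[ResidualRule] = []
    for i, s in enumerate(names):
        targets = names[i + 1 :] + [DEAD]
        # Dirichlet rows: first component is the (residual) stay mass
        alpha = np.concatenate(([6.0], np.full(len(targets), 1.0)))
        rows = rng.dirichlet(alpha, size=k)  # k years x (1 + n_targets)
        for j, to in enumerate(targets):
            clock = TIME_IN_STATE if k > 1 else MODEL_TIME
            transitions.append(
                TransitionSpec(s, to, TimeIndexedValue(rows[:, j + 1]), clock)
            )
        residual_rules.append(ResidualRule(s, s))

    costs = {
        s: CostSchedule(
            s,
            TimeIndexedValue(rng.gamma(2.0, spec.cost_scale, size=k)),
            TIME_IN_STATE if k > 1 else MODEL_TIME,
        )
        for s in names
    }
    utilities = {
        s: float(rng.uniform(spec.utility_low, spec.utility_high)) for s in names
    }
    utilities[DEAD] = 0.0

    config = ModelConfig(
        strategy=f"synthetic_{spec.seed}",
        perspective="synthetic",
        states=states,
        transitions=transitions,
        residual_rules=residual_rules,
        cost_schedules=costs,
        utilities=utilities,
        initial_one_time_cost=float(rng.gamma(2.0, spec.cost_scale)),
        discount_rate=spec.discount_rate,
        horizon_cycles=spec.horizon_cycles,
        start_distribution={names[0]: 1.0},
    )
    return validate(config)


@dataclass
class MicrosimResult:
    """Per-patient discounted payoff summaries from the microsimulation."""

    n_patients: int
    mean_cost: float
    mean_qaly: float
    mean_lyg: float
    sd_cost: float
    sd_qaly: float
    sd_lyg: float

    @property
    def se_cost(self) -> float:
        return self._se(self.sd_cost)

    @property
    def se_qaly(self) -> float:
        return self._se(self.sd_qaly)

    @property
    def se_lyg(self) -> float:
        return self._se(self.sd_lyg)

    def _se(self, sd: float) -> float:
        # SE undefined for a single patient
        return sd / math.sqrt(self.n_patients) if self.n_patients > 1 else math.nan


def microsimulate(
    config: ModelConfig,
    n_patients: int,
    seed: int = 0,
    space: ExpandedStateSpace | None = None,
) -> MicrosimResult:
    """Simulate individual trajectories and aggregate discounted payoffs.

    Patients move through the expanded state space with the same per-cycle
    matrices as the cohort model; payoffs use the same accrual and
    discounting conventions (including the half-cycle toggle, realised as a
    half payoff in the state left and a half in the state entered).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if space is None:
        space = expand_tunnels(config)
    rng = np.random.default_rng(seed)
    n = space.size

    state = np.zeros(n_patients, dtype=np.int64)
    start_states = list(config.start_distribution.items())
    if len(start_states) == 1:
        state[:] = space.entry_index[start_states[0][0]]
    else:
        idx = [space.entry_index[s] for s, _ in start_states]
        probs = np.array([p for _, p in start_states])
        state = rng.choice(idx, size=n_patients, p=probs / probs.sum())

    w = discount_weights(config)
    dt = config.cycle_length_years
    cost = np.full(n_patients, config.initial_one_time_cost)
    qaly = np.zeros(n_patients)
    lyg = np.zeros(n_patients)

    for t in range(1, config.horizon_cycles + 1):
        m = build_matrix(config, space, t)
        cost_a, util_a, alive_a = payoff_arrays(config, space, t)
        next_state = np.empty_like(state)
        for s in np.unique(state):
            mask = state == s
            next_state[mask] = rng.choice(n, size=int(mask.sum()), p=m[s])
        if config.half_cycle_correction:
            occ_cost = 0.5 * (cost_a[state] + cost_a[next_state])
            occ_util = 0.5 * (util_a[state] + util_a[next_state])
            occ_alive = 0.5 * (alive_a[state] + alive_a[next_state])
        else:
            occ_cost = cost_a[state]
            occ_util = util_a[state]
            occ_alive = alive_a[state]
        cost += w[t - 1] * occ_cost
        qaly += w[t - 1] * dt * occ_util
        lyg += w[t - 1] * dt * occ_alive
        state = next_state

    ddof = 1 if n_patients > 1 else 0
    return MicrosimResult(
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        mean_lyg=float(lyg.mean()),
        sd_cost=float(cost.std(ddof=ddof)),
        sd_qaly=float(qaly.std(ddof=ddof)),
        sd_lyg=float(lyg.std(ddof=ddof)),
    )
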