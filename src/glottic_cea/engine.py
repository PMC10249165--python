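"""Markov cohort engine: tunnel expansion, per-cycle matrices, trace, payoffs.

The cohort model advances an occupancy vector over an expanded state space in
which every state with a time-in-state-clocked quantity is replaced by K
tunnel copies (K = longest such vector on the state).  Tunnel copy j routes
its "stay" mass to copy min(j+1, K), so the tail copy is self-referential and
carries the year-K (constant-extension) probabilities and costs.

Payoff conventions (both configurable on :class:`~.params.ModelConfig`):

* cycle ``t`` accrues on start-of-cycle occupancy, optionally averaged with
  end-of-cycle occupancy (``half_cycle_correction``);
* the discount weight of cycle ``t`` is ``(1+r)^-(t-1)`` by default, or
  ``(1+r)^-t`` with ``discount_first_cycle``;
* the one-time initial cost is paid undiscounted by the whole cohort at
  model entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DEAD, MODEL_TIME, TIME_IN_STATE, ModelConfig

ROW_TOL = 1e-9  # |row sum - 1| beyond this is a hard error


class InfeasibleRowError(ValueError):
    """A transition row's explicit mass exceeds 1 (names state and cycle)."""


@dataclass(frozen=True)
class ExpandedStateSpace:
    """Ordered tunnel-resolved state space.

    ``expanded`` lists (base_state, tunnel_index) pairs; ``tunnel_index`` is
    None for untunnelled states.  The dead state is last and never tunnelled.
    """

    expanded: tuple[tuple[str, int | None], ...]
    index: dict[tuple[str, int | None], int]
    entry_index: dict[str, int]  # base state -> expanded index of its entry copy
    tunnel_length: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.expanded)

    def labels(self) -> list[str]:
        return [
            base if j is None else f"{base}_{j}" for base, j in self.expanded
        ]

    def base_occupancy(self, occupancy: np.ndarray) -> dict[str, float]:
        """Collapse an expanded occupancy vector onto base states."""
        out: dict[str, float] = {}
        for (base, _), x in zip(self.expanded, occupancy):
            out[base] = out.get(base, 0.0) + float(x)
        return out


def _needs_tunnel(config: ModelConfig, state: str) -> int:
    """Tunnel length for a state: longest time-in-state vector on it (else 0)."""
    k = 0
    for t in config.explicit_transitions_from(state):
        if t.clock == TIME_IN_STATE:
            k = max(k, len(t.probability))
    sched = config.cost_schedules.get(state)
    if sched is not None and sched.clock == TIME_IN_STATE:
        k = max(k, len(sched.yearly_costs))
    return k


def expand_tunnels(config: ModelConfig) -> ExpandedStateSpace:
    """Expand every state with time-in-state-clocked quantities into tunnels."""
    expanded: list[tuple[str, int | None]] = []
    tunnel_length: dict[str, int] = {}
    for s in config.transient_states:
        k = _needs_tunnel(config, s)
        tunnel_length[s] = k
        if k <= 1:
            # K=1 tunnels behave identically to an untunnelled state
            expanded.append((s, None) if k == 0 else (s, 1))
        else:
            expanded.extend((s, j) for j in range(1, k + 1))
    expanded.append((DEAD, None))
    index = {sj: i for i, sj in enumerate(expanded)}
    entry = {}
    for s in config.transient_states:
        entry[s] = index[(s, None) if tunnel_length[s] == 0 else (s, 1)]
    entry[DEAD] = index[(DEAD, None)]
    return ExpandedStateSpace(tuple(expanded), index, entry, tunnel_length)


def _clock_year(clock: str, cycle: int, tunnel_year: int) -> int:
    return cycle if clock == MODEL_TIME else tunnel_year


def build_matrix(
    config: ModelConfig, space: ExpandedStateSpace, cycle: int
) -> np.ndarray:
    """Row-stochastic transition matrix over the expanded space for one cycle.

    Tunnel copy j evaluates time-in-state quantities at clock year j and
    routes residual "stay" mass to copy min(j+1, K); model-time quantities
    use ``cycle``.  Rows off by more than ``ROW_TOL`` raise
    :class:`InfeasibleRowError`; smaller drift is renormalised.
    """
    if not (1 <= cycle <= config.horizon_cycles):
        raise ValueError(f"cycle must be in 1..{config.horizon_cycles}, got {cycle}")
    n = space.size
    m = np.zeros((n, n))
    dead_i = space.entry_index[DEAD]
    m[dead_i, dead_i] = 1.0

    for i, (base, j) in enumerate(space.expanded):
        if base == DEAD:
            continue
        tunnel_year = 1 if j is None else j
        k = space.tunnel_length[base]
        explicit_total = 0.0
        for t in config.explicit_transitions_from(base):
            p = t.probability.at(_clock_year(t.clock, cycle, tunnel_year))
            explicit_total += p
            if t.to_state == base:
                m[i, _advance_index(space, base, j, k)] += p
            else:
                m[i, space.entry_index[t.to_state]] += p
        residual = 1.0 - explicit_total
        if residual < -ROW_TOL:
            raise InfeasibleRowError(
                f"explicit mass {explicit_total:.12g} > 1 for state {base!r} "
                f"(tunnel year {tunnel_year}) at cycle {cycle}"
            )
        residual = max(residual, 0.0)
        rule = config.residual_rule_for(base)
        if rule.residual_to == base:
            m[i, _advance_index(space, base, j, k)] += residual
        else:
            m[i, space.entry_index[rule.residual_to]] += residual

    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_TOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InfeasibleRowError(
            f"row {space.labels()[bad]!r} sums to {sums[bad]:.12g} at cycle {cycle}"
        )
    return m / sums[:, None]


def _advance_index(
    space: ExpandedStateSpace, base: str, j: int | None, k: int
) -> int:
    if j is None or k <= 1:
        return space.index[(base, j)]
    return space.index[(base, min(j + 1, k))]


@dataclass
class CohortTrace:
    """Per-cycle occupancy of the expanded state space (rows 0..horizon)."""

    config: ModelConfig
    space: ExpandedStateSpace
    occupancy: np.ndarray  # shape (horizon+1, n_expanded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, columns=self.space.labels()
        ).rename_axis(index="cycle")

    def dead_fraction(self) -> np.ndarray:
        return self.occupancy[:, self.space.entry_index[DEAD]]


def run_cohort(config: ModelConfig, space: ExpandedStateSpace | None = None) -> CohortTrace:
    """Advance the cohort: row 0 is the start distribution, row t = row t-1 · M(t)."""
    if space is None:
        space = expand_tunnels(config)
    occ = np.zeros(space.size)
    for s, p in config.start_distribution.items():
        occ[space.entry_index[s]] += p
    rows = [occ]
    for t in range(1, config.horizon_cycles + 1):
        occ = occ @ build_matrix(config, space, t)
        rows.append(occ)
    return CohortTrace(config, space, np.array(rows))


@dataclass
class RunTotals:
    """Discounted totals for one strategy run."""

    strategy: str
    perspective: str
    total_cost: float
    total_qaly: float
    total_lyg: float
    per_cycle: pd.DataFrame  # cycle, discount_weight, cost, qaly, lyg

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "perspective": self.perspective,
            "cost": self.total_cost,
            "qaly": self.total_qaly,
            "lyg": self.total_lyg,
        }


def payoff_arrays(
    config: ModelConfig, space: ExpandedStateSpace, cycle: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-expanded-state (cost, utility, alive) accrual rates for one cycle."""
    n = space.size
    cost = np.zeros(n)
    util = np.zeros(n)
    alive = np.zeros(n)
    for i, (base, j) in enumerate(space.expanded):
        if base == DEAD:
            continue
        tunnel_year = 1 if j is None else j
        sched = config.cost_schedules.get(base)
        if sched is not None:
            cost[i] = sched.yearly_costs.at(
                _clock_year(sched.clock, cycle, tunnel_year)
            )
        util[i] = config.utilities.get(base, 0.0)
        alive[i] = 1.0
    return cost, util, alive


def discount_weights(config: ModelConfig) -> np.ndarray:
    """Discount weight of cycles 1..horizon."""
    r = config.discount_rate
    t = np.arange(1, config.horizon_cycles + 1, dtype=float)
    exponent = t if config.discount_first_cycle else t - 1.0
    return (1.0 + r) ** (-exponent)


def accumulate(config: ModelConfig, trace: CohortTrace) -> RunTotals:
    """Accumulate discounted cost, QALY and life-years over the trace."""
    space = trace.space
    w = discount_weights(config)
    dt = config.cycle_length_years
    rows = []
    total_cost = config.initial_one_time_cost
    total_qaly = 0.0
    total_lyg = 0.0
    for t in range(1, config.horizon_cycles + 1):
        occ = trace.occupancy[t - 1]
        if config.half_cycle_correction:
            occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t])
        cost_a, util_a, alive_a = payoff_arrays(config, space, t)
        c = float(occ @ cost_a) * w[t - 1]
        q = float(occ @ util_a) * dt * w[t - 1]
        l = float(occ @ alive_a) * dt * w[t - 1]
        rows.append((t, w[t - 1], c, q, l))
        total_cost += c
        total_qaly += q
        total_lyg += l
    per_cycle = pd.DataFrame(
        rows, columns=["cycle", "discount_weight", "cost", "qaly", "lyg"]
    )
    return RunTotals(
        config.strategy, config.perspective, total_cost, total_qaly, total_lyg,
        per_cycle,
    )


def run_model(config: ModelConfig) -> RunTotals:
    """Convenience: expand, run and accumulate in one call."""
    return accumulate(config, run_cohort(config))
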