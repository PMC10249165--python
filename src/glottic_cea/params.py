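"""Declarative parameter space for tunnel-state Markov cohort models.

A :class:`ModelConfig` is a complete, serialisable description of one
strategy/perspective model instance: health states, time-indexed transition
probabilities, per-state yearly cost schedules, utilities, discounting and
horizon, plus the distributional assumptions used by the probabilistic
sensitivity analysis.

Two clocks exist.  A quantity clocked by ``model_time`` is looked up with the
current cycle number; a quantity clocked by ``time_in_state`` is looked up
with the number of cycles spent in the state, which the engine realises by
expanding the state into a chain of tunnel copies.  Time-indexed vectors are
extended past their last tabulated year at a constant value (the year-K value
applies to every later year).

Transition rows are closed by a :class:`ResidualRule`: the probability mass
left after all explicit outgoing transitions is routed to the rule's target
(routing to the source state itself means "stay", i.e. advance one tunnel
year).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

DEAD = "dead"

MODEL_TIME = "model_time"
TIME_IN_STATE = "time_in_state"
_CLOCKS = (MODEL_TIME, TIME_IN_STATE)

_FAMILIES = ("beta", "gamma", "fixed")


class ValidationError(ValueError):
    """A model definition violates a structural or numeric invariant."""


@dataclass(frozen=True)
class TimeIndexedValue:
    """Ordered per-year values (year 1..K) with constant extension beyond K."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 1:
            raise ValidationError("TimeIndexedValue requires at least one value")

    def at(self, year: int) -> float:
        """Value for clock year ``year`` (1-based); constant beyond year K."""
        if year < 1:
            raise ValueError(f"clock year must be >= 1, got {year}")
        return self.values[min(year, len(self.values)) - 1]

    def __len__(self) -> int:
        return len(self.values)


def _as_tiv(v) -> TimeIndexedValue:
    if isinstance(v, TimeIndexedValue):
        return v
    if isinstance(v, (int, float)):
        return TimeIndexedValue((float(v),))
    return TimeIndexedValue(tuple(v))


@dataclass(frozen=True)
class TransitionSpec:
    """One explicit transition with a time-indexed probability."""

    from_state: str
    to_state: str
    probability: TimeIndexedValue
    clock: str = MODEL_TIME

    def __post_init__(self) -> None:
        object.__setattr__(self, "probability", _as_tiv(self.probability))
        if self.clock not in _CLOCKS:
            raise ValidationError(f"unknown clock {self.clock!r}")


@dataclass(frozen=True)
class ResidualRule:
    """Residual probability mass of ``from_state`` goes to ``residual_to``."""

    from_state: str
    residual_to: str


@dataclass(frozen=True)
class CostSchedule:
    """Per-year cost (R$/year) of occupying a state."""

    state: str
    yearly_costs: TimeIndexedValue
    clock: str = TIME_IN_STATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "yearly_costs", _as_tiv(self.yearly_costs))
        if self.clock not in _CLOCKS:
            raise ValidationError(f"unknown clock {self.clock!r}")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling description (family, mean, SD) for one parameter or vector.

    For a time-indexed vector the ``mean`` records the vector average; the
    per-year means come from the base config and ``sd`` is the vector-level
    sampling SD applied to every year.
    """

    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.sd < 0:
            raise ValidationError("distribution sd must be >= 0")
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            raise ValidationError(
                f"beta distribution requires mean in (0,1), got {self.mean}"
            )
        if self.family == "gamma" and self.mean <= 0:
            raise ValidationError(
                f"gamma distribution requires mean > 0, got {self.mean}"
            )


@dataclass
class ModelConfig:
    """Complete declarative description of one strategy-perspective model."""

    strategy: str
    perspective: str
    states: tuple[str, ...]
    transitions: list[TransitionSpec]
    residual_rules: list[ResidualRule]
    cost_schedules: dict[str, CostSchedule]
    utilities: dict[str, float]
    initial_one_time_cost: float = 0.0
    discount_rate: float = 0.05
    horizon_cycles: int = 15
    cycle_length_years: float = 1.0
    start_distribution: dict[str, float] = field(default_factory=dict)
    wtp_qaly: float = 40_000.0
    wtp_lyg: float = 35_000.0
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    half_cycle_correction: bool = False
    discount_first_cycle: bool = False

    # -- convenience ------------------------------------------------------

    @property
    def transient_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != DEAD)

    def explicit_transitions_from(self, state: str) -> list[TransitionSpec]:
        return [t for t in self.transitions if t.from_state == state]

    def residual_rule_for(self, state: str) -> ResidualRule:
        for r in self.residual_rules:
            if r.from_state == state:
                return r
        raise KeyError(f"no residual rule for state {state!r}")

    def max_years(self) -> int:
        """Longest time-indexed vector anywhere in the model."""
        n = 1
        for t in self.transitions:
            n = max(n, len(t.probability))
        for c in self.cost_schedules.values():
            n = max(n, len(c.yearly_costs))
        return n

    def copy(self) -> "ModelConfig":
        return dataclasses.replace(
            self,
            transitions=list(self.transitions),
            residual_rules=list(self.residual_rules),
            cost_schedules=dict(self.cost_schedules),
            utilities=dict(self.utilities),
            start_distribution=dict(self.start_distribution),
            psa_specs=dict(self.psa_specs),
        )


# ---------------------------------------------------------------------------
# validation


def resolve_probability(
    config: ModelConfig, from_state: str, to_state: str, clock_time: int
) -> float:
    """Transition probability at a clock year, residual rules included.

    ``clock_time`` is interpreted on each transition's own clock (the caller
    supplies the appropriate year).  Beyond the last tabulated year the value
    is constant.
    """
    if clock_time < 1:
        raise ValueError("clock_time must be >= 1")
    if from_state == DEAD:
        return 1.0 if to_state == DEAD else 0.0
    explicit = config.explicit_transitions_from(from_state)
    for t in explicit:
        if t.to_state == to_state:
            return t.probability.at(clock_time)
    rule = config.residual_rule_for(from_state)
    if rule.residual_to == to_state:
        return 1.0 - sum(t.probability.at(clock_time) for t in explicit)
    return 0.0


def validate(config: ModelConfig) -> ModelConfig:
    """Validate all structural and numeric invariants; returns the config.

    Raises :class:`ValidationError` naming the offending key, state or year.
    """
    seen = set()
    for s in config.states:
        if s in seen:
            raise ValidationError(f"duplicate state label {s!r}")
        seen.add(s)
    if DEAD not in config.states:
        raise ValidationError(f"model must declare the absorbing state {DEAD!r}")

    for s, u in config.utilities.items():
        if s not in config.states:
            raise ValidationError(f"utilities: unknown state {s!r}")
        if not (0.0 <= u <= 1.0):
            raise ValidationError(f"utility of {s!r} out of range [0,1]: {u}")
    if config.utilities.get(DEAD, 0.0) != 0.0:
        raise ValidationError("utility of the dead state must be 0")
    for s in config.transient_states:
        if s not in config.utilities:
            raise ValidationError(f"missing utility for state {s!r}")

    for s, sched in config.cost_schedules.items():
        if s not in config.states:
            raise ValidationError(f"cost_schedules: unknown state {s!r}")
        for y, c in enumerate(sched.yearly_costs.values, start=1):
            if c < 0:
                raise ValidationError(f"negative cost for state {s!r}, year {y}: {c}")
    if config.initial_one_time_cost < 0:
        raise ValidationError("initial_one_time_cost must be >= 0")

    for t in config.transitions:
        for s in (t.from_state, t.to_state):
            if s not in config.states:
                raise ValidationError(f"transition references unknown state {s!r}")
        if t.from_state == DEAD:
            raise ValidationError("the dead state cannot have outgoing transitions")
        for y, p in enumerate(t.probability.values, start=1):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"probability {t.from_state!r}->{t.to_state!r}, "
                    f"year {y} out of [0,1]: {p}"
                )

    for r in config.residual_rules:
        for s in (r.from_state, r.residual_to):
            if s not in config.states:
                raise ValidationError(f"residual rule references unknown state {s!r}")
    for s in config.transient_states:
        rules = [r for r in config.residual_rules if r.from_state == s]
        if len(rules) != 1:
            raise ValidationError(
                f"state {s!r} must have exactly one residual rule, found {len(rules)}"
            )

    # residual probability >= 0 at every clock year
    horizon_years = max(config.max_years(), config.horizon_cycles)
    for s in config.transient_states:
        explicit = config.explicit_transitions_from(s)
        for y in range(1, horizon_years + 1):
            total = sum(t.probability.at(y) for t in explicit)
            if total > 1.0 + 1e-12:
                raise ValidationError(
                    f"explicit outgoing probabilities of state {s!r} sum to "
                    f"{total:.6g} > 1 in year {y}"
                )

    if config.horizon_cycles < 1:
        raise ValidationError("horizon_cycles must be >= 1")
    if config.discount_rate < 0:
        raise ValidationError("discount_rate must be >= 0")

    if not config.start_distribution:
        raise ValidationError("start_distribution is empty")
    total = sum(config.start_distribution.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValidationError(f"start_distribution sums to {total}, expected 1")
    for s, p in config.start_distribution.items():
        if s not in config.states:
            raise ValidationError(f"start_distribution: unknown state {s!r}")
        if p < 0:
            raise ValidationError(f"start_distribution[{s!r}] < 0")

    return config


# ---------------------------------------------------------------------------
# (de)serialisation — JSON-compatible hierarchical dialect


def to_dict(config: ModelConfig) -> dict:
    return {
        "strategy": config.strategy,
        "perspective": config.perspective,
        "states": list(config.states),
        "transitions": [
            {
                "from": t.from_state,
                "to": t.to_state,
                "probability": list(t.probability.values),
                "clock": t.clock,
            }
            for t in config.transitions
        ],
        "residual_rules": [
            {"from": r.from_state, "to": r.residual_to} for r in config.residual_rules
        ],
        "cost_schedules": {
            s: {"yearly_costs": list(c.yearly_costs.values), "clock": c.clock}
            for s, c in config.cost_schedules.items()
        },
        "utilities": dict(config.utilities),
        "initial_one_time_cost": config.initial_one_time_cost,
        "discount_rate": config.discount_rate,
        "horizon_cycles": config.horizon_cycles,
        "cycle_length_years": config.cycle_length_years,
        "start_distribution": dict(config.start_distribution),
        "wtp_qaly": config.wtp_qaly,
        "wtp_lyg": config.wtp_lyg,
        "psa_specs": {
            k: {"family": d.family, "mean": d.mean, "sd": d.sd}
            for k, d in config.psa_specs.items()
        },
        "half_cycle_correction": config.half_cycle_correction,
        "discount_first_cycle": config.discount_first_cycle,
    }


def from_dict(d: Mapping) -> ModelConfig:
    try:
        config = ModelConfig(
            strategy=d["strategy"],
            perspective=d["perspective"],
            states=tuple(d["states"]),
            transitions=[
                TransitionSpec(
                    t["from"], t["to"], _as_tiv(t["probability"]),
                    t.get("clock", MODEL_TIME),
                )
                for t in d["transitions"]
            ],
            residual_rules=[
                ResidualRule(r["from"], r["to"]) for r in d["residual_rules"]
            ],
            cost_schedules={
                s: CostSchedule(s, _as_tiv(c["yearly_costs"]),
                                c.get("clock", TIME_IN_STATE))
                for s, c in d["cost_schedules"].items()
            },
            utilities={s: float(u) for s, u in d["utilities"].items()},
            initial_one_time_cost=float(d.get("initial_one_time_cost", 0.0)),
            discount_rate=float(d.get("discount_rate", 0.05)),
            horizon_cycles=int(d.get("horizon_cycles", 15)),
            cycle_length_years=float(d.get("cycle_length_years", 1.0)),
            start_distribution={
                s: float(p) for s, p in d["start_distribution"].items()
            },
            wtp_qaly=float(d.get("wtp_qaly", 40_000.0)),
            wtp_lyg=float(d.get("wtp_lyg", 35_000.0)),
            psa_specs={
                k: DistributionSpec(v["family"], float(v["mean"]), float(v["sd"]))
                for k, v in d.get("psa_specs", {}).items()
            },
            half_cycle_correction=bool(d.get("half_cycle_correction", False)),
            discount_first_cycle=bool(d.get("discount_first_cycle", False)),
        )
    except KeyError as e:
        raise ValidationError(f"missing required config key: {e.args[0]!r}") from e
    return validate(config)


def load_config(path) -> ModelConfig:
    """Load and validate a model definition file (JSON)."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"config file is not valid JSON: {e}") from e
    return from_dict(d)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# parameter addressing (shared by DSA and PSA)
#
# Parameter ids:
#   "initial_cost"
#   "cost:<state>"
#   "utility:<state>"
#   "prob:<from>-><to>"        (explicit transitions only)


def parameter_values(config: ModelConfig, param: str) -> tuple[float, ...]:
    """Current value(s) of an addressed parameter (per-year tuple or 1-tuple)."""
    if param == "initial_cost":
        return (config.initial_one_time_cost,)
    kind, _, rest = param.partition(":")
    if kind == "cost":
        return config.cost_schedules[rest].yearly_costs.values
    if kind == "utility":
        return (config.utilities[rest],)
    if kind == "prob":
        frm, _, to = rest.partition("->")
        for t in config.transitions:
            if t.from_state == frm and t.to_state == to:
                return t.probability.values
        raise KeyError(f"no explicit transition {frm!r}->{to!r}")
    raise KeyError(f"unknown parameter id {param!r}")


def with_parameter_values(
    config: ModelConfig, param: str, values: Iterable[float]
) -> ModelConfig:
    """New config with the addressed parameter replaced by ``values``.

    ``values`` must have the same length as the existing vector (or length 1
    for scalars).  Probabilities are clamped to [0,1] and costs to >= 0 by the
    caller where appropriate; this function performs a plain substitution.
    """
    values = tuple(float(v) for v in values)
    out = config.copy()
    if param == "initial_cost":
        (out.initial_one_time_cost,) = values
        return out
    kind, _, rest = param.partition(":")
    if kind == "cost":
        sched = out.cost_schedules[rest]
        out.cost_schedules[rest] = CostSchedule(
            sched.state, TimeIndexedValue(values), sched.clock
        )
        return out
    if kind == "utility":
        (out.utilities[rest],) = values
        return out
    if kind == "prob":
        frm, _, to = rest.partition("->")
        for i, t in enumerate(out.transitions):
            if t.from_state == frm and t.to_state == to:
                out.transitions[i] = TransitionSpec(
                    t.from_state, t.to_state, TimeIndexedValue(values), t.clock
                )
                return out
        raise KeyError(f"no explicit transition {frm!r}->{to!r}")
    raise KeyError(f"unknown parameter id {param!r}")


def with_parameter_scaled(
    config: ModelConfig, param: str, factor: float
) -> ModelConfig:
    """Scale a parameter (every year of a vector) by a common factor.

    Probabilities are clamped to [0,1]; costs to >= 0.
    """
    base = parameter_values(config, param)
    is_prob = param.startswith(("prob:", "utility:"))
    scaled = []
    for v in base:
        x = v * factor
        if is_prob:
            x = min(max(x, 0.0), 1.0)
        else:
            x = max(x, 0.0)
        scaled.append(x)
    return with_parameter_values(config, param, scaled)
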