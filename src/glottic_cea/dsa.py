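"""One-way deterministic sensitivity analysis with tornado ranking.

Each Table-style input row is treated as one tornado bar: a time-indexed
vector is perturbed by a single multiplicative factor applied to every year,
preserving its shape.  Cost parameters range over ±40% of base; probability
and utility parameters over mean ± 1.96·SD (vector-level SD), clamped to
[0,1].  Variation can target one strategy arm or both (e.g. "initial cost of
CFRT" raises only the CFRT arm while both arms share the base value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cea import incremental_analysis
from .engine import run_model
from .params import ModelConfig, parameter_values, with_parameter_scaled
from .psa import clamp_to_simplex

log = logging.getLogger(__name__)

PCT40 = "pct40"
CONFIDENCE_INTERVAL = "confidence_interval"
EXPLICIT = "explicit"

BOTH = "both"


@dataclass(frozen=True)
class DSARange:
    """Low/high bound for one parameter, on the scale of its vector mean."""

    parameter: str
    base: float  # scalar value or vector mean
    low: float
    high: float
    source: str
    arm: str = BOTH  # strategy name, or "both"

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range for {self.parameter!r} must satisfy low <= base <= high"
            )

    @property
    def low_factor(self) -> float:
        return self.low / self.base if self.base else 1.0

    @property
    def high_factor(self) -> float:
        return self.high / self.base if self.base else 1.0


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    arm: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _vector_mean(values: tuple[float, ...]) -> float:
    return sum(values) / len(values)


def default_ranges(
    ref: ModelConfig, comp: ModelConfig, z: float = 1.96
) -> list[DSARange]:
    """Tornado ranges for every PSA-specified parameter of a strategy pair.

    Costs: base × 0.6 / 1.4, varied per strategy arm.  Probabilities and
    utilities: mean ± z·SD clamped to [0,1]; parameters whose base values
    coincide in both arms vary jointly, strategy-specific ones per arm.
    """
    ranges: list[DSARange] = []
    for param, spec in ref.psa_specs.items():
        base_ref = _vector_mean(parameter_values(ref, param))
        base_comp = _vector_mean(parameter_values(comp, param))
        shared = base_ref == base_comp
        if spec.family == "gamma":  # cost parameter
            arms = (BOTH,) if False else (ref.strategy, comp.strategy)
            for arm, base in zip(arms, (base_ref, base_comp)):
                ranges.append(
                    DSARange(param, base, 0.6 * base, 1.4 * base, PCT40, arm)
                )
        else:
            delta = z * spec.sd
            if shared:
                lo = max(base_ref - delta, 0.0)
                hi = min(base_ref + delta, 1.0)
                ranges.append(
                    DSARange(param, base_ref, lo, hi, CONFIDENCE_INTERVAL, BOTH)
                )
            else:
                for arm, base in ((ref.strategy, base_ref), (comp.strategy, base_comp)):
                    lo = max(base - delta, 0.0)
                    hi = min(base + delta, 1.0)
                    ranges.append(
                        DSARange(param, base, lo, hi, CONFIDENCE_INTERVAL, arm)
                    )
    return ranges


def _perturb(config: ModelConfig, rng: DSARange, factor: float) -> ModelConfig:
    if rng.arm not in (BOTH, config.strategy):
        return config
    try:
        out = with_parameter_scaled(config, rng.parameter, factor)
    except KeyError:
        return config
    if rng.parameter.startswith("prob:"):
        out, n_clamped = clamp_to_simplex(out)
        if n_clamped:
            log.warning(
                "perturbing %s by %.3f broke the probability simplex in %d "
                "year(s); clamped", rng.parameter, factor, n_clamped,
            )
    return out


def one_way(
    ref: ModelConfig, comp: ModelConfig, rng: DSARange, wtp_qaly: float | None = None
) -> TornadoEntry:
    """ICER (comparator − reference, per QALY) at the range's low and high."""
    wtp = wtp_qaly if wtp_qaly is not None else ref.wtp_qaly
    icers = []
    for factor in (rng.low_factor, rng.high_factor):
        res = incremental_analysis(
            run_model(_perturb(ref, rng, factor)),
            run_model(_perturb(comp, rng, factor)),
            wtp,
        )
        icers.append(res.icer_qaly)
    return TornadoEntry(
        rng.parameter, rng.arm, rng.low, rng.high, icers[0], icers[1]
    )


def tornado(
    ref: ModelConfig,
    comp: ModelConfig,
    ranges: list[DSARange] | None = None,
) -> list[TornadoEntry]:
    """One-way results for every range, sorted by descending ICER span."""
    if ranges is None:
        ranges = default_ranges(ref, comp)
    entries = [one_way(ref, comp, r) for r in ranges]
    return sorted(entries, key=lambda e: e.span, reverse=True)
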