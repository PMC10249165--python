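"""Incremental cost-effectiveness analysis between two strategies.

Deltas follow the comparator-minus-reference convention (here CFRT relative
to HYPOFRT).  The ICER is reported signed even when one strategy dominates —
a negative ICER is not decision-relevant on its own, so a dominance class is
carried alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import RunTotals

COMPARATOR_DOMINATED = "comparator_dominated"  # reference cheaper & more effective
INTERVENTION_DOMINATED = "intervention_dominated"
TRADEOFF = "tradeoff"


def nmb(totals: RunTotals, wtp: float) -> float:
    """Net monetary benefit wtp·QALY − cost at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * totals.total_qaly - totals.total_cost


@dataclass
class CEAResult:
    reference: RunTotals
    comparator: RunTotals
    delta_cost: float
    delta_qaly: float
    delta_lyg: float
    icer_qaly: float  # NaN when delta_qaly == 0
    icer_lyg: float
    dominance: str
    nmb_reference: float
    nmb_comparator: float
    wtp_qaly: float

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer_qaly)

    def as_dict(self) -> dict:
        return {
            "reference": self.reference.as_dict(),
            "comparator": self.comparator.as_dict(),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_lyg": self.delta_lyg,
            "icer_qaly": None if math.isnan(self.icer_qaly) else self.icer_qaly,
            "icer_lyg": None if math.isnan(self.icer_lyg) else self.icer_lyg,
            "dominance": self.dominance,
            "nmb_reference": self.nmb_reference,
            "nmb_comparator": self.nmb_comparator,
            "wtp_qaly": self.wtp_qaly,
        }


def classify_dominance(delta_cost: float, delta_effect: float) -> str:
    """Dominance class from the signs of (comparator − reference) deltas.

    The comparator is dominated when it costs more and yields less; the
    reference (intervention) is dominated in the mirror case.  Everything
    else — including ties on either axis — is a trade-off to be judged
    against a willingness-to-pay threshold.
    """
    if delta_cost > 0 and delta_effect < 0:
        return COMPARATOR_DOMINATED
    if delta_cost < 0 and delta_effect > 0:
        return INTERVENTION_DOMINATED
    return TRADEOFF


def incremental_analysis(
    ref: RunTotals, comp: RunTotals, wtp_qaly: float = 40_000.0
) -> CEAResult:
    """Compare two runs: deltas, signed ICERs, dominance, NMB at ``wtp_qaly``."""
    d_cost = comp.total_cost - ref.total_cost
    d_qaly = comp.total_qaly - ref.total_qaly
    d_lyg = comp.total_lyg - ref.total_lyg
    icer_q = d_cost / d_qaly if d_qaly != 0 else math.nan
    icer_l = d_cost / d_lyg if d_lyg != 0 else math.nan
    dominance = classify_dominance(d_cost, d_qaly)
    if d_qaly == 0:
        # ICER undefined: decide on cost alone
        dominance = COMPARATOR_DOMINATED if d_cost > 0 else (
            INTERVENTION_DOMINATED if d_cost < 0 else TRADEOFF
        )
    return CEAResult(
        reference=ref,
        comparator=comp,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_lyg=d_lyg,
        icer_qaly=icer_q,
        icer_lyg=icer_l,
        dominance=dominance,
        nmb_reference=nmb(ref, wtp_qaly),
        nmb_comparator=nmb(comp, wtp_qaly),
        wtp_qaly=wtp_qaly,
    )
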