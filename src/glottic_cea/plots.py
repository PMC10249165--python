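"""Convenience figures: cost-effectiveness plane, CEAC, NMB and tornado."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .dsa import TornadoEntry
from .psa import PSAOutput


def ce_plane(psa: PSAOutput, ax=None, wtp: float | None = None):
    """Scatter of per-iteration (ΔQALY, Δcost), comparator vs reference."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(
        psa.iterations["delta_qaly"], psa.iterations["delta_cost"],
        s=4, alpha=0.3, linewidths=0,
    )
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    if wtp is not None:
        xs = psa.iterations["delta_qaly"]
        ax.plot([xs.min(), xs.max()], [wtp * xs.min(), wtp * xs.max()],
                "--", color="grey", lw=0.8, label=f"WTP {wtp:,.0f}")
        ax.legend()
    ax.set_xlabel(f"incremental QALY ({psa.comparator} − {psa.reference})")
    ax.set_ylabel("incremental cost (R$)")
    return ax


def ceac_curve(psa: PSAOutput, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    for name in (psa.reference, psa.comparator):
        ax.plot(psa.ceac["wtp"], psa.ceac[f"p_{name.lower()}"], label=name)
    ax.set_xlabel("willingness-to-pay (R$/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def nmb_curve(psa: PSAOutput, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    for name in (psa.reference, psa.comparator):
        ax.plot(psa.nmb_curves["wtp"], psa.nmb_curves[f"nmb_{name.lower()}"],
                label=name)
    ax.set_xlabel("willingness-to-pay (R$/QALY)")
    ax.set_ylabel("mean net monetary benefit (R$)")
    ax.legend()
    return ax


def tornado_plot(entries: list[TornadoEntry], base_icer: float, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1))
    labels = [f"{e.parameter} [{e.arm}]" for e in entries][::-1]
    for y, e in enumerate(entries[::-1]):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="tab:blue", alpha=0.7)
    ax.axvline(base_icer, color="k", lw=0.8)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel("ICER (R$/QALY)")
    return ax
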