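"""Base-case cost-effectiveness of HYPOFRT vs CFRT, both payer perspectives.

Runs the 15-cycle Markov cohort model on the embedded case-study inputs and
prints discounted totals, increments and the signed ICER.  A negative ICER
with the "comparator_dominated" flag means conventional fractionation costs
more *and* yields fewer QALYs — hypofractionation dominates.
"""

from glottic_cea import fixture_pair, incremental_analysis, run_model

for perspective in ("public", "private"):
    ref, comp = fixture_pair(perspective)
    h, c = run_model(ref), run_model(comp)
    res = incremental_analysis(h, c, wtp_qaly=ref.wtp_qaly)
    print(f"--- {perspective} health system (R$) ---")
    for t in (h, c):
        print(f"{t.strategy:8s} cost {t.total_cost:10,.2f}  "
              f"QALY {t.total_qaly:6.3f}  LYG {t.total_lyg:6.3f}")
    print(f"CFRT - HYPOFRT: dCost {res.delta_cost:,.2f}  "
          f"dQALY {res.delta_qaly:.3f}  dLYG {res.delta_lyg:.3f}")
    print(f"ICER {res.icer_qaly:,.2f} R$/QALY, {res.icer_lyg:,.2f} R$/LYG "
          f"[{res.dominance}]")
    print(f"NMB at R$40,000/QALY: HYPOFRT {res.nmb_reference:,.0f}  "
          f"CFRT {res.nmb_comparator:,.0f}  "
          f"(ratio {res.nmb_reference / res.nmb_comparator:.2f})\n")
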