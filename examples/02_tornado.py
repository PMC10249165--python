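"""One-way deterministic sensitivity analysis (tornado) for the public payer.

Each input is swung to its low/high bound (costs ±40%, probabilities and
utilities mean ± 1.96·SD) one at a time; the bars are ranked by how far the
ICER moves.  Wide bars identify the inputs that drive the decision.
"""

from glottic_cea import fixture_pair, incremental_analysis, run_model, tornado

ref, comp = fixture_pair("public")
base = incremental_analysis(run_model(ref), run_model(comp))
print(f"base-case ICER: {base.icer_qaly:,.2f} R$/QALY\n")
print(f"{'parameter':45s} {'arm':8s} {'ICER low':>12s} {'ICER high':>12s} {'span':>10s}")
for e in tornado(ref, comp)[:10]:
    print(f"{e.parameter:45s} {e.arm:8s} {e.icer_at_low:12,.2f} "
          f"{e.icer_at_high:12,.2f} {e.span:10,.2f}")
print("\nCost inputs dominate the ranking: the decision is driven by what "
      "each payer reimburses, not by the clinical transition probabilities.")
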