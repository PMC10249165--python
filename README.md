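# glottic-cea

Cost-effectiveness modelling of radiotherapy fractionation for early-stage
glottic (vocal-cord) cancer, built as a reusable tunnel-state Markov cohort
toolkit for health economists and radiation oncology researchers.

## The problem

Early-stage glottic cancer (T1–2N0M0) is curable with definitive
radiotherapy. Two schedules compete: **hypofractionation** (HYPOFRT,
2.25 Gy/fraction, ~25–28 fractions) and **conventional fractionation**
(CFRT, 2 Gy/fraction, ~30–33 fractions). Randomised evidence shows better
five-year local control with hypofractionation, and both Brazilian payers —
the public SUS and the private CBHPM schedules — reimburse radiotherapy at a
fixed price per course regardless of fraction count. Whether HYPOFRT is
*cost-effective* is therefore a question about downstream salvage surgery,
metastatic disease and quality of life, which this package answers with a
Markov cohort model of a 65-year-old male cohort.

## The model

Four health states: `controlled_disease` (CD), `local_failure` (LF, salvaged
by total laryngectomy), `distant_failure` (DF) and absorbing `dead`. Each
yearly cycle, a patient in CD stays with probability *s_t* (strategy-specific,
tabulated for years 1–5 and constant afterwards), dies of background causes
with probability 0.03, or suffers a local failure with the residual
probability 1 − *s_t* − 0.03. The LF and DF processes depend on *time since
entering the state*, implemented with **tunnel states**: K=5 chained copies
per state whose tail copy is self-referential, so the year-5 probabilities
and costs extend to all later years.

Discounted totals per strategy accumulate

- cost: one-time radiotherapy reimbursement + per-state yearly costs,
- QALYs: state utility × years lived,
- LYG: undiscounted-utility life-years,

each at 5 %/year over a 15-year horizon. Strategies are compared by the
incremental cost-effectiveness ratio ICER = ΔC/ΔE (comparator − reference,
reported signed even under dominance), dominance class, and net monetary
benefit NMB(λ) = λ·E − C against the Brazilian thresholds (R$40,000/QALY,
R$35,000/LYG). Uncertainty is handled by one-way deterministic sensitivity
analysis (costs ±40 %, probabilities/utilities mean ± 1.96·SD, tornado
ranking) and probabilistic sensitivity analysis (method-of-moments beta/gamma
distributions, correlated arms, shared quantile per time-indexed vector,
CEAC and NMB curves over a willingness-to-pay grid).

A synthetic-model generator and an independent individual-level
microsimulation oracle make every stage testable: on any random valid model
the cohort expectation must agree with the mean of 10⁵ simulated patients.

## Worked example

```python
from glottic_cea import fixture_pair, incremental_analysis, run_model

ref, comp = fixture_pair("public")           # HYPOFRT, CFRT configs
h, c = run_model(ref), run_model(comp)
res = incremental_analysis(h, c, wtp_qaly=40_000)
```

Running `python examples/01_base_case.py` prints (public perspective):

```
HYPOFRT  cost   7,739.93  QALY  7.292  LYG  8.927
CFRT     cost   8,674.24  QALY  6.129  LYG  8.315
CFRT - HYPOFRT: dCost 934.32  dQALY -1.164  dLYG -0.612
ICER -802.90 R$/QALY, -1,527.01 R$/LYG [comparator_dominated]
NMB at R$40,000/QALY: HYPOFRT 283,955  CFRT 236,474  (ratio 1.20)
```

Read: over 15 discounted years a hypofractionated patient costs R$934 less
and gains 1.16 QALYs relative to conventional fractionation, so CFRT is
*dominated* — the negative ICER is reported for completeness but the
dominance flag is the decision-relevant output. The same holds from the
private perspective with a much larger cost difference (ΔC ≈ R$10,178).
`examples/02_tornado.py` shows the ranking is driven by the cost inputs,
and `examples/03_psa_ceac.py` propagates parameter uncertainty:
P(HYPOFRT cost-effective) ≈ 0.96 at R$2,000/QALY (public). See
`docs/methods.md` for conventions, assumptions and a detailed account of how
these figures relate to the originally reported case-study results.

Other entry points: the `glottic-cea` CLI (`run`, `dsa`, `psa`, `fixture`,
`synth`, `microsim`, `validate`) writes documented CSV/JSON outputs with a
reproducibility manifest, and `glottic_cea.plots` renders the CE plane,
CEAC, NMB and tornado figures.

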