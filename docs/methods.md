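# Methods

## Model structure

The package implements a discrete-time Markov cohort model for a homogeneous
cohort of 65-year-old men treated with definitive radiotherapy for
early-stage glottic cancer. Four base health states:

- **controlled_disease (CD)** — alive, no evidence of disease; the whole
  cohort starts here.
- **local_failure (LF)** — local recurrence salvaged by total laryngectomy
  with neck dissection; remaining in LF means living post-salvage in
  remission.
- **distant_failure (DF)** — metastatic disease on adjuvant chemotherapy.
- **dead** — absorbing; the only state with utility 0 and no outgoing
  transitions.

Allowed transitions are progressive: CD→{CD, LF, dead}, LF→{LF, DF, dead},
DF→{DF, dead}. The two strategies (HYPOFRT, CFRT) differ **only** in the
probability of remaining in CD; the failure process, utilities and yearly
state costs are shared, and both payers reimburse the radiotherapy course at
the same fixed price for either schedule.

### Residual rules

Published inputs specify the *stay* probability for CD and the *exit*
probabilities for LF and DF; the remaining mass of each row is closed by a
declared residual rule. For CD the residual 1 − stay − 0.03 is the local
failure probability (the only closure consistent with the state topology:
background death 0.03 applies in CD, and the stay probability is printed).
For LF and DF the residual is "stay", realised as a tunnel advance.
Validation rejects any configuration whose explicit mass exceeds 1 in any
clock year, naming the state and year.

The 0.03 background mortality is applied only in CD; the LF and DF death
probabilities are treated as all-cause. Whether the original analysis added
background mortality in the failure states is unknown; the effect is second
order relative to the tabulated failure-state mortality.

### Tunnel states and clocks

Every quantity carries a clock: `model_time` (lookup by cycle number) or
`time_in_state` (lookup by years since entering the state). A state with any
time-in-state quantity is expanded into K tunnel copies, K being the longest
such vector on the state (K=5 in the canonical model, giving a 12-state
expanded space: CD, LF₁–LF₅, DF₁–DF₅, dead). Copy j evaluates its
probabilities and costs at clock year j and routes its stay mass to copy
min(j+1, K); the tail copy is self-referential, which realises the
"constant from year 5 onwards" extension of all tabulated vectors. CD costs
are clocked by model time — equivalent to time-in-state because CD is never
re-entered — so CD needs no tunnel. LF/DF costs are time-in-state-clocked so
that the expensive first year (salvage surgery R$1,804.23 public /
R$20,838.67 private; chemotherapy R$5,400.76 / R$24,211.79) is paid on entry
regardless of the calendar year.

## Payoff and discounting conventions

For cycle t = 1..15 (cycle length 1 year):

- payoffs accrue on **start-of-cycle occupancy**; the `half_cycle_correction`
  toggle (default **off**) averages start- and end-of-cycle occupancy
  instead, approximating mid-cycle event timing;
- the discount weight is **(1+r)^−(t−1)** with r = 0.05/year; the
  `discount_first_cycle` toggle (default **off**) switches to (1+r)^−t;
- each alive state accrues cost(state, clock year) R$/year, utility·1 year
  of QALYs and 1 life-year, all × occupancy × discount weight;
- the one-time initial cost is paid undiscounted by 100 % of the cohort at
  model entry.

The defaults mirror the common cohort-software convention (no half-cycle
correction, stage-0 payment undiscounted). Both toggles are honoured
identically by the cohort engine and the microsimulation, and by every CLI
subcommand. Rates r → 0 recover undiscounted sums exactly, and QALY ≤ LYG
whenever all utilities ≤ 1.

Numerical tolerances: transition rows must sum to 1 within 1e−9 (smaller
drift is renormalised, larger is a hard error naming state and cycle); trace
rows conserve mass within 1e−9; the dead fraction is non-decreasing.

## Canonical inputs

The embedded case-study inputs (two strategies × two perspectives):

| input | value (SD) |
|---|---|
| stay in CD, HYPOFRT, y1–5 | 0.97 / 0.96 / 0.94 / 0.94 / 0.93 (0.014) |
| stay in CD, CFRT, y1–5 | 0.94 / 0.90 / 0.85 / 0.81 / 0.77 (0.07) |
| CD→dead | 0.03 (0.014) |
| LF→DF, y1–5 since failure | 0.008 / 0.017 / 0.026 / 0.034 / 0.043 (0.013) |
| LF→dead, y1–5 | 0.025 / 0.049 / 0.073 / 0.09 / 0.12 (0.037) |
| DF→dead, y1–5 | 0.601893 / 0.84 / 0.93 / 0.97 / 0.99 (0.14) |
| utilities CD / LF / DF | 0.85 (0.017) / 0.57 (0.060) / 0.42 (0.006) |
| initial cost public / private | 4,168.00 (1,667.2) / 37,396.24 (14,958.49) R$ |
| yearly state costs | see `glottic_cea.fixtures` (SDs per vector) |
| discount, horizon, WTP | 5 %/yr, 15 × 1-year cycles, R$40,000/QALY & R$35,000/LYG |

The printed SD of each time-indexed vector is interpreted as the sampling SD
of *every* year in the vector (the public CD-cost SD 301.42 equals the
sample SD of its five yearly values, supporting this reading). Printed USD
equivalents are stored as static annotations only; nothing recomputes
currency conversions.

## Deterministic sensitivity analysis

One tornado bar per input row. Cost parameters swing to base × 0.6 / 1.4;
probabilities and utilities to mean ± 1.96·SD clamped to [0,1]. A
time-indexed vector is perturbed by a single multiplicative factor
(1 ± 1.96·SD/vector-mean for probability vectors) applied to all years,
preserving its shape. Variation is strategy-specific for parameters whose
base values differ between arms or that the narrative varies per arm (cost
inputs); parameters shared by construction vary jointly. Perturbations that
break a probability row's simplex are clamped onto it and logged, so tornado
runs always complete. Two closed-form identities serve as internal checks:
varying a cost shared by both arms leaves the ICER unchanged, and raising
only the reference arm's one-time cost by δ moves the ICER by exactly
−δ/ΔE.

## Probabilistic sensitivity analysis

Distributions are fitted by the method of moments: beta for probabilities
and utilities (ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν), gamma for costs
(shape = m²/s², scale = s²/m). Fits invert exactly — the analytic mean/SD of
every fitted distribution equals its source values to 1e−9 — with one
documented exception: where the vector-level SD is infeasible at a given
year's mean (the DF→dead years 0.93–0.99 with SD 0.14 exceed the Bernoulli
bound √(m(1−m))), the SD is clamped to 95 % of the bound for that year and
the clamp is counted. `beta_from_moments` itself refuses infeasible moments
with an error suggesting the clamp.

Per iteration:

- each time-indexed vector is drawn with **one shared quantile** — a single
  uniform deviate mapped through each year's fitted distribution — so years
  remain comonotone and stochastically ordered vectors keep their clinical
  ordering (independent-per-year draws, available behind
  `shared_quantile=False`, could invert the monotone failure process);
- parameters whose base values coincide in both arms (utilities, failure
  probabilities, costs, initial cost) use the **same draw in both arms**;
  the strategy-specific stay vectors are drawn independently
  (`correlated=False` breaks all arm coupling);
- after substitution the CD→LF residual is re-resolved automatically; any
  row whose explicit mass exceeds 1 (e.g. a high stay draw plus a high
  background-death draw) is rescaled onto the simplex and counted in
  `n_clamped`.

Default 10,000 iterations, WTP grid 0–50,000 R$/QALY in steps of 500, a
single seeded `numpy` generator recorded in all outputs; repeated runs with
the same seed are byte-identical. CEAC(λ) is the fraction of iterations in
which a strategy attains the maximum λ·QALY − cost (the two probabilities
sum to 1 by construction); NMB curves are per-λ means.

## Synthetic models and the microsimulation oracle

`generate_random_model` draws valid configurations by construction: 2–5
transient states with a progressive topology, per-year Dirichlet transition
rows (stay mass as the residual), gamma-distributed positive costs,
uniform utilities in [0.2, 1], one absorbing dead state, deterministic under
its seed. It emulates the *structure* of real cohort models — tunnels,
time-varying hazards, skewed costs — but not their clinical content: rows
are exchangeable rather than clinically ordered, there is no arm pairing,
and costs are independent of transitions. Passing the generator-based tests
therefore demonstrates the correctness of the machinery on arbitrary valid
inputs, not the realism of any particular clinical parameterisation.

`microsimulate` is the independent oracle: it simulates individual patient
trajectories with the same per-cycle matrices and payoff rules (vectorised
per-cycle multinomial updates from one root-seeded generator) and aggregates
per-patient discounted payoffs with mean, SD and SE = SD/√n (SE is NaN for
n = 1). It shares only the matrix-builder and payoff contracts with the
cohort engine — not the trace code path — so agreement is a genuine
cross-check. The test suite requires cohort totals within 3·SE of the
microsimulation mean on 20 random models at n = 10⁵ patients each, and on
the canonical fixtures at n = 2×10⁵; these sizes keep each check well under
a second while giving cost SEs of ~R$15 on totals of ~R$10,000.

## Reproduction of the originally reported base case

The package reproduces the *decision* of the original case study — HYPOFRT
dominates CFRT from both perspectives, robustly across DSA and PSA — and its
incremental costs closely (public ΔC R$934 vs R$985 reported; private
R$10,178 vs R$10,695). It does **not** reproduce the reported absolute
effect values (QALYs 6.50 vs 2.78, LYG 8.06 vs 4.42) or the ICER magnitudes
derived from them, under any setting of the half-cycle and discount-timing
toggles, and the discrepancy is provably not a convention issue:

- The two arms share every input except the CD stay vector, so the CD
  occupancy path is fixed by the products of the printed stay probabilities.
  Discounted CD-only person-time is then 7.89 (HYPOFRT) and 5.02 (CFRT)
  years under start-of-cycle accrual (7.07/4.04 end-of-cycle, 7.48/4.53
  half-cycle).
- The reported HYPOFRT LYG (8.06) *exceeds* its CD-only person-time except
  under start-of-cycle accrual, so patients leaving CD must survive for
  years; the reported CFRT LYG (4.42) is *below* its CD-only person-time
  under two of the three accrual conventions and barely above it under the
  third, so CFRT leavers must die almost immediately. CFRT leavers exit
  earlier (at higher discount weight), so any shared failure process gives
  them *more* discounted per-exit survival than HYPOFRT leavers — the
  reported pair is unreachable with arm-shared failure inputs.
- The reported ICERs are internally consistent (all four imply
  ΔQALY = 3.7256 and ΔLYG = 3.6360), so the original model genuinely
  produced those effect deltas — evidently from arm-asymmetric structure or
  inputs beyond the published table (its supplementary model file is not
  available). With the published inputs this implementation obtains
  ΔQALY = 1.16 and ΔLYG = 0.61.

Consequences, all left visible in the test suite rather than hidden: the
base-case totals computed here (public: 7,739.93 / 8,674.24 R$, QALY
7.29 / 6.13, LYG 8.93 / 8.31 at the default toggles) differ from the
reported table; the one-way DSA spot value for the +40 % HYPOFRT initial
cost is ≈630 R$/QALY rather than the reported 183.18 (the closed-form
identity (ΔC − δ)/ΔQ holds exactly in both cases — the difference is
entirely the ΔQ in the denominator); the reported NMB ratios (2.4 public,
5.2 private) are not reached (1.20 / 1.40 here; note the reported private
ratio 5.2 is also inconsistent with the reported totals themselves, which
imply ≈8.1); and the CEAC at R$2,000/QALY is ≈0.96 rather than 0.9999,
because the probability of a sign flip in ΔNMB scales with the ΔQALY
margin. The corresponding acceptance tests assert the reported values
faithfully and are expected to fail until the source discrepancy is
resolved; the structural acceptance test (oracle agreement, moment
inversion, conservation, discount limit, ICER invariance, seeded
reproducibility) passes.

## Design choices where the design was open

- **Signed ICERs under dominance**, with the dominance class alongside:
  matches how such tables are usually printed while flagging that a
  dominated comparison's ICER is not decision-relevant.
- **Incremental direction** fixed as CFRT − HYPOFRT (comparator −
  reference).
- **Stay-vector draws independent across arms** in the PSA: the two
  schedules' control rates come from different trial arms; correlating them
  would understate decision uncertainty.
- **Generalised state labels**: any label set with a designated absorbing
  `dead` state is accepted, so the generator and user models are not limited
  to the four case-study states.
- **Tunnel length per state** (the longest time-in-state vector on that
  state) rather than one global K: equivalent on the canonical model,
  cheaper on heterogeneous synthetic models.
- **Problem sizes in tests**: PSA checks run at n = 2,000 (CEAC values at
  n = 2,000 and n = 10,000 agree to ~±0.01); oracle checks at n = 10⁵
  patients × 20 models.

## Known limitations

- No age-dependent background mortality table; the 0.03/year CD death
  probability is constant, and the 15-cycle horizon truncates rather than
  extrapolates lifetime outcomes.
- No half-cycle correction of the one-time entry cost (it is a point
  payment by definition).
- The PSA treats the vector-level SD as the SD of every year; per-year SDs
  are not published.
- Two-strategy comparisons only; no efficiency frontier over >2 strategies,
  no EVPI, no partitioned-survival variant.
- Female cohorts and carotid-sparing technique effects are out of scope, as
  in the original analysis.
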