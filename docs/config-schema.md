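# Model definition file schema

Model instances are plain JSON, loaded with `glottic_cea.load_config` and
written with `save_config` (round-trip stable). The `glottic-cea fixture`
subcommand writes the four canonical files as worked examples.

```jsonc
{
  "strategy": "HYPOFRT",            // free label for this arm
  "perspective": "public",          // free label for the payer
  "states": ["controlled_disease", "local_failure",
             "distant_failure", "dead"],
  // "dead" is mandatory: the unique absorbing state, utility 0

  "transitions": [                  // explicit transitions only
    {
      "from": "controlled_disease",
      "to": "controlled_disease",   // "to" == "from" means stay
      "probability": [0.97, 0.96, 0.94, 0.94, 0.93],
      // per-year values, year 1..K; the year-K value applies to
      // every later year (constant extension); a single value means
      // a constant probability
      "clock": "model_time"         // or "time_in_state" (tunnel)
    }
  ],

  "residual_rules": [               // exactly one per transient state:
    {"from": "controlled_disease",  // 1 - sum(explicit) goes here;
     "to": "local_failure"},        // "to" == "from" means stay
    {"from": "local_failure", "to": "local_failure"},
    {"from": "distant_failure", "to": "distant_failure"}
  ],

  "cost_schedules": {               // R$/year per occupied state
    "local_failure": {
      "yearly_costs": [1804.23, 707.16, 220.41, 220.41, 220.41],
      "clock": "time_in_state"
    }
  },

  "utilities": {"controlled_disease": 0.85, "local_failure": 0.57,
                "distant_failure": 0.42, "dead": 0.0},   // all in [0,1]

  "initial_one_time_cost": 4168.00, // paid undiscounted at entry
  "discount_rate": 0.05,            // per year
  "horizon_cycles": 15,
  "cycle_length_years": 1.0,
  "start_distribution": {"controlled_disease": 1.0},  // sums to 1
  "wtp_qaly": 40000.0,
  "wtp_lyg": 35000.0,

  "psa_specs": {                    // sampling spec per parameter id
    // ids: "initial_cost", "cost:<state>", "utility:<state>",
    //      "prob:<from>-><to>"
    "utility:controlled_disease": {"family": "beta",
                                   "mean": 0.85, "sd": 0.017},
    "initial_cost": {"family": "gamma", "mean": 4168.0, "sd": 1667.2}
    // families: "beta" (probabilities/utilities), "gamma" (costs),
    // "fixed" (no sampling); for a time-indexed vector the per-year
    // means come from the config and "sd" applies to every year
  },

  "half_cycle_correction": false,   // average start/end occupancy
  "discount_first_cycle": false     // (1+r)^-t instead of (1+r)^-(t-1)
}
```

Validation (run on load, and via `glottic-cea validate <file>`) enforces:
unique state labels including `dead`; utilities in [0,1] with dead = 0;
non-negative costs; probabilities in [0,1] with explicit outgoing mass ≤ 1
in every clock year (errors name the state and year); exactly one residual
rule per transient state; a start distribution summing to 1; horizon ≥ 1;
beta specs with mean in (0,1); gamma specs with positive mean.
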