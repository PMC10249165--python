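"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: every parameter with a
:class:`~.params.DistributionSpec` is drawn from a beta (probabilities,
utilities) or gamma (costs) distribution fitted by the method of moments to
its mean and SD, both strategy models are re-run per draw, and the
per-iteration incremental results feed the cost-effectiveness acceptability
curve (CEAC) and mean net-monetary-benefit curves over a willingness-to-pay
grid.

Sampling scheme:

* a time-indexed vector is drawn with one shared quantile — a single uniform
  deviate mapped through each year's fitted distribution — preserving the
  clinically monotone ordering of the years (an independent-per-year mode is
  available behind ``shared_quantile=False``);
* parameters whose base values coincide in both strategies (utilities,
  failure-process probabilities, costs) use the same draw in both arms;
  strategy-specific parameters (the stay probabilities) are drawn
  independently (``correlated=False`` breaks the arm coupling entirely);
* draws that push a state's explicit outgoing mass above 1 are rescaled onto
  the simplex and counted in ``n_clamped``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import discount_weights, expand_tunnels, payoff_arrays, run_cohort
from .params import (
    DistributionSpec,
    ModelConfig,
    parameter_values,
    with_parameter_values,
)

log = logging.getLogger(__name__)

DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 50_001, 500))
_BETA_SD_CLAMP = 0.95  # fraction of the Bernoulli SD bound used when clamping


@dataclass(frozen=True)
class FittedDistribution:
    """A beta/gamma/fixed distribution with analytically matched moments."""

    family: str
    params: tuple[float, ...]  # beta: (alpha, beta); gamma: (shape, scale)
    mean: float
    sd: float

    def ppf(self, u):
        if self.family == "beta":
            return stats.beta.ppf(u, *self.params)
        if self.family == "gamma":
            a, scale = self.params
            return stats.gamma.ppf(u, a, scale=scale)
        return np.full_like(np.asarray(u, dtype=float), self.mean)

    def analytic_moments(self) -> tuple[float, float]:
        if self.family == "beta":
            a, b = self.params
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1))
            return m, math.sqrt(v)
        if self.family == "gamma":
            a, scale = self.params
            return a * scale, math.sqrt(a) * scale
        return self.mean, 0.0


def beta_from_moments(mean: float, sd: float) -> FittedDistribution:
    """Beta(α, β) with the given mean and SD.

    ν = mean(1−mean)/sd² − 1,  α = mean·ν,  β = (1−mean)·ν.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie in (0,1), got {mean}")
    if sd <= 0:
        raise ValueError("beta sd must be > 0 (use family='fixed' for sd=0)")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise ValueError(
            f"variance {sd*sd:.6g} is not below the Bernoulli bound "
            f"mean(1-mean)={bound:.6g}; clamp the SD below "
            f"{math.sqrt(bound):.6g} to fit a beta"
        )
    nu = bound / (sd * sd) - 1.0
    return FittedDistribution("beta", (mean * nu, (1.0 - mean) * nu), mean, sd)


def gamma_from_moments(mean: float, sd: float) -> FittedDistribution:
    """Gamma(shape, scale) with the given mean and SD: shape = mean²/sd²."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be > 0")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return FittedDistribution("gamma", (shape, scale), mean, sd)


def fit_yearly(
    spec: DistributionSpec, year_mean: float
) -> tuple[FittedDistribution, bool]:
    """Fit the spec's family at one year's mean with the vector-level SD.

    Returns (distribution, clamped).  A beta whose variance exceeds the
    Bernoulli bound at this year's mean gets its SD clamped to 95% of the
    bound (e.g. a death probability of 0.99 with SD 0.14).
    """
    if spec.family == "fixed" or spec.sd == 0:
        return FittedDistribution("fixed", (), year_mean, 0.0), False
    if spec.family == "gamma":
        if year_mean <= 0:
            return FittedDistribution("fixed", (), year_mean, 0.0), False
        return gamma_from_moments(year_mean, spec.sd), False
    # beta
    if not (0.0 < year_mean < 1.0):
        return FittedDistribution("fixed", (), year_mean, 0.0), False
    bound_sd = math.sqrt(year_mean * (1.0 - year_mean))
    if spec.sd >= bound_sd:
        clamped_sd = _BETA_SD_CLAMP * bound_sd
        log.debug(
            "beta SD %.4g infeasible at mean %.4g; clamped to %.4g",
            spec.sd, year_mean, clamped_sd,
        )
        return beta_from_moments(year_mean, clamped_sd), True
    return beta_from_moments(year_mean, spec.sd), False


# ---------------------------------------------------------------------------
# drawing


def _draw_vector(
    spec: DistributionSpec,
    base_values: tuple[float, ...],
    rng: np.random.Generator,
    shared_quantile: bool,
) -> tuple[list[float], int]:
    """One draw of a (possibly time-indexed) parameter; returns (values, n_clamped_fits)."""
    n_clamped = 0
    if shared_quantile:
        u = np.full(len(base_values), rng.uniform())
    else:
        u = rng.uniform(size=len(base_values))
    out = []
    for ui, m in zip(u, base_values):
        dist, clamped = fit_yearly(spec, m)
        n_clamped += clamped
        out.append(float(dist.ppf(ui)))
    return out, n_clamped


def clamp_to_simplex(config: ModelConfig) -> tuple[ModelConfig, int]:
    """Rescale any year where a state's explicit outgoing mass exceeds 1."""
    n_events = 0
    years = config.max_years()
    out = config
    for s in config.transient_states:
        explicit = out.explicit_transitions_from(s)
        if not explicit:
            continue
        k = max(len(t.probability) for t in explicit)
        totals = [
            sum(t.probability.at(y) for t in explicit)
            for y in range(1, max(k, years) + 1)
        ]
        if all(tot <= 1.0 for tot in totals):
            continue
        for t in explicit:
            vals = [
                t.probability.at(y) / max(totals[y - 1], 1.0)
                for y in range(1, len(t.probability) + 1)
            ]
            out = with_parameter_values(
                out, f"prob:{t.from_state}->{t.to_state}", vals
            )
        n_events += sum(tot > 1.0 for tot in totals)
        log.debug("clamped explicit mass >1 for state %r", s)
    return out, n_events


def draw_parameter_set(
    config: ModelConfig,
    rng: np.random.Generator,
    shared_quantile: bool = True,
) -> ModelConfig:
    """One joint parameter draw for a single strategy config."""
    out = config
    for param in sorted(config.psa_specs):
        spec = config.psa_specs[param]
        base = parameter_values(config, param)
        vals, _ = _draw_vector(spec, base, rng, shared_quantile)
        if spec.family == "beta":
            vals = [min(max(v, 0.0), 1.0) for v in vals]
        out = with_parameter_values(out, param, vals)
    out, _ = clamp_to_simplex(out)
    return out


@dataclass
class PSAOutput:
    """Per-iteration results plus CEAC and NMB curves over a WTP grid."""

    seed: int
    n_iterations: int
    wtp_grid: tuple[float, ...]
    iterations: pd.DataFrame  # iteration, cost/qaly/lyg per strategy, deltas
    ceac: pd.DataFrame        # wtp, p_<ref>, p_<comp>
    nmb_curves: pd.DataFrame  # wtp, nmb_<ref>, nmb_<comp>
    reference: str
    comparator: str
    n_clamped: int = 0

    def ceac_at(self, wtp: float, strategy: str | None = None) -> float:
        """CEAC probability (reference strategy by default) at one WTP value."""
        col = f"p_{(strategy or self.reference).lower()}"
        idx = (self.ceac["wtp"] - wtp).abs().idxmin()
        return float(self.ceac.loc[idx, col])


def _totals_fast(config: ModelConfig, space) -> tuple[float, float, float]:
    trace = run_cohort(config, space)
    w = discount_weights(config)
    dt = config.cycle_length_years
    cost = config.initial_one_time_cost
    qaly = 0.0
    lyg = 0.0
    for t in range(1, config.horizon_cycles + 1):
        occ = trace.occupancy[t - 1]
        if config.half_cycle_correction:
            occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t])
        cost_a, util_a, alive_a = payoff_arrays(config, space, t)
        cost += float(occ @ cost_a) * w[t - 1]
        qaly += float(occ @ util_a) * dt * w[t - 1]
        lyg += float(occ @ alive_a) * dt * w[t - 1]
    return cost, qaly, lyg


def run_psa(
    ref: ModelConfig,
    comp: ModelConfig,
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
    shared_quantile: bool = True,
    correlated: bool = True,
) -> PSAOutput:
    """Monte Carlo PSA over a strategy pair.

    Per iteration one joint parameter set is drawn (shared parameters once,
    strategy-specific ones per arm), both cohort models are re-run, and the
    (cost, QALY, LYG) triples are recorded.  CEAC(λ) is the fraction of
    iterations in which each strategy attains the maximum λ·QALY − cost.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    params = sorted(ref.psa_specs)
    shared = {
        p: parameter_values(ref, p) == parameter_values(comp, p)
        for p in params
        if p in comp.psa_specs
    }
    space_ref = expand_tunnels(ref)
    space_comp = expand_tunnels(comp)

    rows = []
    n_clamped = 0
    for i in range(n):
        cfg_r, cfg_c = ref, comp
        for p in params:
            spec = ref.psa_specs[p]
            vals_r, _ = _draw_vector(
                spec, parameter_values(ref, p), rng, shared_quantile
            )
            if spec.family == "beta":
                vals_r = [min(max(v, 0.0), 1.0) for v in vals_r]
            cfg_r = with_parameter_values(cfg_r, p, vals_r)
            if p in comp.psa_specs:
                if correlated and shared[p]:
                    vals_c = vals_r
                else:
                    vals_c, _ = _draw_vector(
                        comp.psa_specs[p], parameter_values(comp, p), rng,
                        shared_quantile,
                    )
                    if comp.psa_specs[p].family == "beta":
                        vals_c = [min(max(v, 0.0), 1.0) for v in vals_c]
                cfg_c = with_parameter_values(cfg_c, p, vals_c)
        cfg_r, k1 = clamp_to_simplex(cfg_r)
        cfg_c, k2 = clamp_to_simplex(cfg_c)
        n_clamped += k1 + k2
        c_r, q_r, l_r = _totals_fast(cfg_r, space_ref)
        c_c, q_c, l_c = _totals_fast(cfg_c, space_comp)
        rows.append((i, c_r, q_r, l_r, c_c, q_c, l_c, c_c - c_r, q_c - q_r))

    rname, cname = ref.strategy.lower(), comp.strategy.lower()
    iterations = pd.DataFrame(
        rows,
        columns=[
            "iteration",
            f"cost_{rname}", f"qaly_{rname}", f"lyg_{rname}",
            f"cost_{cname}", f"qaly_{cname}", f"lyg_{cname}",
            "delta_cost", "delta_qaly",
        ],
    )

    wtp = np.asarray(wtp_grid, dtype=float)
    cost_r = iterations[f"cost_{rname}"].to_numpy()
    qaly_r = iterations[f"qaly_{rname}"].to_numpy()
    cost_c = iterations[f"cost_{cname}"].to_numpy()
    qaly_c = iterations[f"qaly_{cname}"].to_numpy()
    nmb_r = wtp[:, None] * qaly_r[None, :] - cost_r[None, :]
    nmb_c = wtp[:, None] * qaly_c[None, :] - cost_c[None, :]
    p_ref = (nmb_r >= nmb_c).mean(axis=1)
    ceac = pd.DataFrame(
        {"wtp": wtp, f"p_{rname}": p_ref, f"p_{cname}": 1.0 - p_ref}
    )
    nmb_curves = pd.DataFrame(
        {
            "wtp": wtp,
            f"nmb_{rname}": nmb_r.mean(axis=1),
            f"nmb_{cname}": nmb_c.mean(axis=1),
        }
    )
    return PSAOutput(
        seed=seed,
        n_iterations=n,
        wtp_grid=tuple(wtp),
        iterations=iterations,
        ceac=ceac,
        nmb_curves=nmb_curves,
        reference=ref.strategy,
        comparator=comp.strategy,
        n_clamped=n_clamped,
    )
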