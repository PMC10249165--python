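"""PSA: method-of-moments fits, joint draws, CEAC/NMB outputs."""

import math

import numpy as np
import pytest

from glottic_cea import (
    beta_from_moments,
    draw_parameter_set,
    gamma_from_moments,
    run_psa,
)
from glottic_cea.params import DistributionSpec, parameter_values
from glottic_cea.psa import clamp_to_simplex, fit_yearly


class TestBetaFromMoments:
    def test_uniform_limit(self):
        d = beta_from_moments(0.5, math.sqrt(1.0 / 12.0))
        a, b = d.params
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_controlled_disease_utility_fit(self):
        d = beta_from_moments(0.85, 0.017)
        a, b = d.params
        assert a == pytest.approx(374.15, abs=0.01)
        assert b == pytest.approx(66.0265, abs=0.01)

    def test_variance_beyond_bernoulli_bound_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            beta_from_moments(0.5, 0.6)

    @pytest.mark.parametrize("mean,sd", [(0.85, 0.017), (0.03, 0.014),
                                         (0.57, 0.06), (0.42, 0.006)])
    def test_exact_moment_inversion(self, mean, sd):
        m, s = beta_from_moments(mean, sd).analytic_moments()
        assert m == pytest.approx(mean, abs=1e-9)
        assert s == pytest.approx(sd, abs=1e-9)


class TestGammaFromMoments:
    def test_public_initial_cost_fit(self):
        d = gamma_from_moments(4_168.00, 1_667.2)
        shape, scale = d.params
        assert shape == pytest.approx(6.25)
        assert scale == pytest.approx(666.88)

    def test_forty_percent_sd_gives_shape_625(self):
        shape, _ = gamma_from_moments(37_396.24, 14_958.49).params
        assert shape == pytest.approx(6.25, rel=1e-4)

    def test_exponential_limit(self):
        shape, scale = gamma_from_moments(500.0, 500.0).params
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(500.0)

    @pytest.mark.parametrize("mean,sd", [(4168.0, 1667.2), (220.41, 687.01)])
    def test_exact_moment_inversion(self, mean, sd):
        m, s = gamma_from_moments(mean, sd).analytic_moments()
        assert m == pytest.approx(mean, rel=1e-12)
        assert s == pytest.approx(sd, rel=1e-12)


class TestFitYearly:
    def test_infeasible_beta_sd_clamped(self):
        # death probability 0.99 with vector SD 0.14 exceeds the bound
        spec = DistributionSpec("beta", 0.8662, 0.14)
        dist, clamped = fit_yearly(spec, 0.99)
        assert clamped
        m, s = dist.analytic_moments()
        assert m == pytest.approx(0.99, abs=1e-9)
        assert s < math.sqrt(0.99 * 0.01)

    def test_feasible_beta_untouched(self):
        spec = DistributionSpec("beta", 0.85, 0.017)
        dist, clamped = fit_yearly(spec, 0.85)
        assert not clamped
        assert dist.analytic_moments()[1] == pytest.approx(0.017, abs=1e-9)


class TestDrawParameterSet:
    def test_zero_sd_returns_base_config(self, hypofrt_public):
        cfg = hypofrt_public.copy()
        cfg.psa_specs = {
            k: DistributionSpec("fixed", v.mean, 0.0)
            for k, v in cfg.psa_specs.items()
        }
        drawn = draw_parameter_set(cfg, np.random.default_rng(0))
        for param in cfg.psa_specs:
            assert parameter_values(drawn, param) == \
                pytest.approx(parameter_values(cfg, param))

    def test_deterministic_under_seed(self, hypofrt_public):
        a = draw_parameter_set(hypofrt_public, np.random.default_rng(42))
        b = draw_parameter_set(hypofrt_public, np.random.default_rng(42))
        for param in hypofrt_public.psa_specs:
            assert parameter_values(a, param) == parameter_values(b, param)

    def test_shared_quantile_draws_are_comonotone(self, cfrt_public):
        """Every year of a vector is drawn at the same quantile of its own
        fitted distribution (so stochastically ordered years keep their
        clinical ordering)."""
        from scipy import stats

        rng = np.random.default_rng(7)
        spec = cfrt_public.psa_specs["prob:local_failure->dead"]
        base = parameter_values(cfrt_public, "prob:local_failure->dead")
        for _ in range(10):
            drawn = draw_parameter_set(cfrt_public, rng)
            vals = parameter_values(drawn, "prob:local_failure->dead")
            levels = []
            for v, m in zip(vals, base):
                dist, _ = fit_yearly(spec, m)
                levels.append(stats.beta.cdf(v, *dist.params))
            np.testing.assert_allclose(levels, levels[0], atol=1e-8)

    def test_stay_vector_ordering_preserved(self, cfrt_public):
        # the stay probabilities are stochastically ordered year over year,
        # so the shared quantile keeps the drawn vector non-increasing
        rng = np.random.default_rng(7)
        for _ in range(25):
            drawn = draw_parameter_set(cfrt_public, rng)
            stay = parameter_values(
                drawn, "prob:controlled_disease->controlled_disease"
            )
            assert all(a >= b - 1e-12 for a, b in zip(stay, stay[1:]))

    def test_sample_mean_matches_source_moments(self, hypofrt_public):
        from glottic_cea.psa import _draw_vector

        rng = np.random.default_rng(11)
        spec = hypofrt_public.psa_specs["utility:controlled_disease"]
        n = 10_000
        draws = np.array(
            [_draw_vector(spec, (0.85,), rng, True)[0][0] for _ in range(n)]
        )
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - 0.85) < 3 * se

    def test_clamp_to_simplex(self, hypofrt_public):
        from glottic_cea.params import with_parameter_values

        bad = with_parameter_values(
            hypofrt_public, "prob:controlled_disease->controlled_disease",
            (0.99,) * 5,
        )
        clamped, n = clamp_to_simplex(bad)
        assert n > 0
        stay = parameter_values(
            clamped, "prob:controlled_disease->controlled_disease"
        )[0]
        death = parameter_values(clamped, "prob:controlled_disease->dead")[0]
        assert stay + death <= 1.0 + 1e-12


class TestRunPSA:
    def test_ceac_probabilities_sum_to_one(self, small_psa):
        total = small_psa.ceac["p_hypofrt"] + small_psa.ceac["p_cfrt"]
        np.testing.assert_allclose(total, 1.0)
        assert ((small_psa.ceac["p_hypofrt"] >= 0)
                & (small_psa.ceac["p_hypofrt"] <= 1)).all()

    def test_iteration_count_recorded(self, small_psa):
        assert small_psa.n_iterations == 120
        assert len(small_psa.iterations) == 120

    def test_seeded_reproducibility_byte_for_byte(self, public_pair):
        ref, comp = public_pair
        a = run_psa(ref, comp, n=40, seed=9, wtp_grid=(2_000.0,))
        b = run_psa(ref, comp, n=40, seed=9, wtp_grid=(2_000.0,))
        assert a.iterations.to_csv() == b.iterations.to_csv()
        assert a.ceac.to_csv() == b.ceac.to_csv()
        assert a.nmb_curves.to_csv() == b.nmb_curves.to_csv()

    def test_single_iteration_degenerate_ceac(self, public_pair):
        ref, comp = public_pair
        out = run_psa(ref, comp, n=1, seed=3, wtp_grid=(0.0, 10_000.0, 40_000.0))
        assert set(out.ceac["p_hypofrt"]).issubset({0.0, 1.0})

    def test_ceac_favours_dominant_strategy_at_threshold(self, small_psa):
        assert small_psa.ceac_at(40_000.0) > 0.5

    def test_nmb_curves_linear_in_wtp(self, small_psa):
        nmb = small_psa.nmb_curves
        qaly_mean = small_psa.iterations["qaly_hypofrt"].mean()
        cost_mean = small_psa.iterations["cost_hypofrt"].mean()
        for _, row in nmb.iterrows():
            assert row["nmb_hypofrt"] == pytest.approx(
                row["wtp"] * qaly_mean - cost_mean, rel=1e-9
            )
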