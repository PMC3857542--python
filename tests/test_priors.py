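"""Prior and group-level (hierarchical) density evaluation."""

import numpy as np
import pytest
from scipy import integrate, stats

from stoprace import (
    HierarchicalState,
    PriorSpec,
    log_group_model,
    log_prior_individual,
)
from stoprace.priors import truncnorm_logpdf
from stoprace.race import PARAM_NAMES


class TestPriorSpec:
    def test_default_bounds_valid(self):
        spec = PriorSpec.default()
        assert spec.bounds["mu_go"] == (1.0, 2000.0)
        assert spec.spread_bounds["tau_stop"] == (0.01, 500.0)

    def test_scale_for_seconds(self):
        spec = PriorSpec.default(scale=0.001)
        assert spec.bounds["mu_go"] == (0.001, 2.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(bounds={**PriorSpec.default().bounds, "mu_go": (5.0, 5.0)})
        bad_spread = dict(PriorSpec.default().spread_bounds)
        bad_spread["mu_go"] = (-1.0, 10.0)
        with pytest.raises(ValueError):
            PriorSpec(spread_bounds=bad_spread)

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "priors.yaml"
        cfg.write_text("scale: 1.0\nbounds:\n  mu_go: [10, 1500]\n")
        spec = PriorSpec.from_yaml(cfg)
        assert spec.bounds["mu_go"] == (10.0, 1500.0)
        assert spec.bounds["sigma_go"] == (1.0, 500.0)


class TestIndividualPrior:
    def test_uniform_density_at_midpoint(self):
        spec = PriorSpec.default()
        expect = -np.sum(np.log(spec.uppers() - spec.lowers()))
        assert log_prior_individual(spec.midpoint(), spec) == pytest.approx(expect)

    def test_out_of_support_flagged(self):
        spec = PriorSpec.default()
        theta = spec.midpoint()
        theta[0] = spec.bounds["mu_go"][1] + 1.0
        assert log_prior_individual(theta, spec) == -np.inf

    def test_prior_draws_uniform(self):
        # chi-square goodness-of-fit of 1e4 draws per parameter over 20 bins
        spec = PriorSpec.default()
        rng = np.random.default_rng(77)
        draws = np.array([spec.sample_individual(rng) for _ in range(10_000)])
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = spec.bounds[name]
            hist, _ = np.histogram(draws[:, j], bins=20, range=(lo, hi))
            chi2 = np.sum((hist - 500.0) ** 2 / 500.0)
            assert chi2 < stats.chi2.ppf(0.999, df=19)


class TestTruncatedNormal:
    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            loc = rng.uniform(0, 600)
            scale = rng.uniform(1, 120)
            lo, hi = 1.0, 2000.0
            x = rng.uniform(lo, hi, size=5)
            a, b = (lo - loc) / scale, (hi - loc) / scale
            expect = stats.truncnorm.logpdf(x, a, b, loc=loc, scale=scale)
            got = truncnorm_logpdf(x, loc, scale, lo, hi)
            np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_normalization_by_quadrature(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            loc = rng.uniform(50, 450)
            scale = rng.uniform(5, 80)
            total, _ = integrate.quad(
                lambda x: np.exp(truncnorm_logpdf(x, loc, scale, 1.0, 500.0)),
                1.0,
                500.0,
                limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_outside_truncation_is_minus_inf(self):
        assert truncnorm_logpdf(0.5, 100.0, 10.0, 1.0, 500.0) == -np.inf


class TestGroupModel:
    def _state(self, subj):
        return HierarchicalState(
            subj=subj,
            loc=np.array([500.0, 50.0, 100.0, 200.0, 20.0, 50.0]),
            spread=np.array([30.0, 10.0, 20.0, 20.0, 5.0, 10.0]),
        )

    def test_participant_at_group_location(self):
        spec = PriorSpec.default()
        state = self._state(np.array([[500.0, 50.0, 100.0, 200.0, 20.0, 50.0]]))
        hyper_const = -(
            np.sum(np.log(spec.uppers("loc_bounds") - spec.lowers("loc_bounds")))
            + np.sum(np.log(spec.uppers("spread_bounds") - spec.lowers("spread_bounds")))
        )
        expect = hyper_const + sum(
            truncnorm_logpdf(
                state.loc[j], state.loc[j], state.spread[j], *spec.bounds[PARAM_NAMES[j]]
            )
            for j in range(6)
        )
        assert log_group_model(state, spec) == pytest.approx(expect)

    def test_tight_group_with_distant_participant_is_penalized(self):
        spec = PriorSpec.default()
        near = self._state(np.array([[500.0, 50.0, 100.0, 200.0, 20.0, 50.0]]))
        far = self._state(np.array([[500.0, 50.0, 100.0, 200.0, 20.0, 50.0]]))
        far.spread = np.full(6, 0.02)
        far.subj[0, 0] += 0.2  # ten spreads away from the location
        assert log_group_model(far, spec) < log_group_model(near, spec) - 10

    def test_hypers_out_of_bounds(self):
        spec = PriorSpec.default()
        state = self._state(np.array([[500.0, 50.0, 100.0, 200.0, 20.0, 50.0]]))
        state.spread = np.full(6, 1e-6)  # below the spread lower bound
        assert log_group_model(state, spec) == -np.inf

    def test_prior_insensitivity_on_diagnostic_data(self, sim_dataset):
        """Widening the prior bounds leaves a well-identified large-n
        posterior essentially unchanged."""
        from stoprace import MCMCSettings, map_start, run_chains
        from stoprace.diagnostics import summarize

        wide = PriorSpec(
            bounds={k: (lo * 0.5 if lo > 1 else lo, hi * 2) for k, (lo, hi) in PriorSpec.default().bounds.items()}
        )
        settings = MCMCSettings(n_chains=2, n_samples=1500, burn_in=600, thin=2, seed=21)
        start = map_start(sim_dataset.arrays(), seed=21)
        base = summarize(run_chains(sim_dataset, PriorSpec.default(), settings, start=start))
        alt = summarize(run_chains(sim_dataset, wide, settings, start=start))
        for name in ("mean_go", "mean_stop"):
            sd = base.loc[name, "sd"]
            assert abs(base.loc[name, "mean"] - alt.loc[name, "mean"]) < 3 * sd
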