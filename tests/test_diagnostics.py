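"""Convergence diagnostics, posterior summaries, DIC, and plot output."""

import re

import numpy as np
import pytest

from stoprace import MCMCSettings, PriorSpec, dic, rhat, rhat_table, summarize
from stoprace.sampler import PosteriorChains

from .oracles import rhat_oracle


def _count_pdf_pages(path) -> int:
    data = path.read_bytes()
    return len(re.findall(rb"/Type\s*/Page[^s]", data))


class TestRhat:
    def test_equals_formula_oracle_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            chains = [rng.normal(size=50) for _ in range(rng.integers(2, 5))]
            assert rhat(chains) == rhat_oracle(chains)

    def test_hand_sized_example(self):
        chains = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 5.0])]
        assert rhat(chains) == pytest.approx(rhat_oracle(chains), rel=0)

    def test_converged_chains_below_rule_of_thumb(self):
        rng = np.random.default_rng(12)
        chains = [rng.normal(size=5000) for _ in range(3)]
        assert rhat(chains) < 1.1

    def test_gross_divergence_detected(self):
        rng = np.random.default_rng(13)
        chains = [rng.normal(0.0, 1.0, 1000), rng.normal(10.0, 1.0, 1000)]
        assert rhat(chains) > 1.1

    def test_error_cases(self):
        with pytest.raises(ValueError):
            rhat([np.arange(10.0)])
        with pytest.raises(ValueError):
            rhat([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            rhat([np.arange(5.0), np.arange(4.0)])


def _chains_from(draws_per_chain, names):
    k = len(draws_per_chain)
    n = draws_per_chain[0].shape[0]
    return PosteriorChains(
        param_names=list(names),
        chains=[np.asarray(d, dtype=float) for d in draws_per_chain],
        deviance=[np.full(n, np.nan) for _ in range(k)],
        settings=MCMCSettings(n_chains=k, n_samples=2 * n, burn_in=n, thin=1),
    )


class TestSummarize:
    def test_constant_draws(self):
        pc = _chains_from([np.full((50, 1), 7.0)], ["mu_go"])
        row = summarize(pc, include_derived=False).loc["mu_go"]
        assert row["mean"] == 7.0 and row["sd"] == 0.0
        assert all(row[f"q{q:g}"] == 7.0 for q in (2.5, 25, 50, 75, 97.5))

    def test_derived_rows_are_draw_wise(self, fitted_chains):
        table = summarize(fitted_chains)
        mu = fitted_chains.column("mu_go")
        tau = fitted_chains.column("tau_go")
        # definitional: summarize(mu + tau) draw-wise, not mean(mu) + mean(tau) recombined
        assert table.loc["mean_go", "mean"] == pytest.approx(np.mean(mu + tau))
        assert table.loc["mean_go", "sd"] == pytest.approx(np.std(mu + tau, ddof=1))
        sig = fitted_chains.column("sigma_stop")
        taus = fitted_chains.column("tau_stop")
        assert table.loc["sd_stop", "mean"] == pytest.approx(
            np.mean(np.sqrt(sig**2 + taus**2))
        )

    def test_normal_quantiles(self):
        rng = np.random.default_rng(30)
        pc = _chains_from([rng.normal(size=(100_000, 1))], ["x"])
        row = summarize(pc, include_derived=False).loc["x"]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)

    def test_concatenation_order_invariant(self, fitted_chains):
        reordered = PosteriorChains(
            param_names=fitted_chains.param_names,
            chains=list(reversed(fitted_chains.chains)),
            deviance=list(reversed(fitted_chains.deviance)),
            settings=fitted_chains.settings,
        )
        a = summarize(fitted_chains)
        b = summarize(reordered)
        for q in ("q2.5", "q50", "q97.5"):
            np.testing.assert_allclose(a[q], b[q], rtol=1e-12)


class TestDic:
    def test_constant_deviance(self):
        d, pd_ = dic(np.full(100, 42.0), 42.0)
        assert pd_ == 0.0 and d == 42.0

    def test_conjugate_normal_effective_parameters(self):
        # y_i ~ N(theta, 1), flat prior: posterior N(ybar, 1/n), pD = 1
        rng = np.random.default_rng(55)
        n, m = 50, 200_000
        y = rng.normal(0.7, 1.0, n)
        theta = rng.normal(y.mean(), 1.0 / np.sqrt(n), m)
        dev = np.array([np.sum((y - t) ** 2) for t in theta])
        dev_at_mean = np.sum((y - theta.mean()) ** 2)
        _, pd_ = dic(dev, dev_at_mean)
        assert pd_ == pytest.approx(1.0, abs=0.05)

    def test_monotone_in_mean_deviance(self):
        base = np.array([10.0, 12.0, 14.0])
        d1, p1 = dic(base, 11.0)
        d2, p2 = dic(base + 5.0, 16.0)
        assert p1 == pytest.approx(p2)
        assert d2 > d1


class TestPlots:
    def test_render_smoke_and_page_count(self, fitted_chains, tmp_path):
        from stoprace.diagnostics import render_plots

        base = str(tmp_path / "run")
        paths = render_plots(fitted_chains, PriorSpec.default(), base)
        for p in paths:
            q = tmp_path / p.split("/")[-1]
            assert q.exists() and q.stat().st_size > 0
        # 6 parameters at 6 panels per page -> one page per document
        assert _count_pdf_pages(tmp_path / "run_posteriors.pdf") == 1
        assert _count_pdf_pages(tmp_path / "run_traces.pdf") == 1

    def test_group_only_mode_plots_group_parameters(self, tmp_path):
        rng = np.random.default_rng(2)
        names = (
            [f"{p}_subj_1" for p in
             ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop")]
            + [f"{p}_group_mean" for p in
               ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop")]
            + [f"{p}_group_sd" for p in
               ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop")]
        )
        pc = _chains_from([rng.normal(size=(40, 18)), rng.normal(size=(40, 18))], names)
        from stoprace.diagnostics import render_plots

        base = str(tmp_path / "grp")
        render_plots(pc, PriorSpec.default(), base, estimates_for="group")
        # 12 group-level parameters -> 2 pages of 6 panels
        assert _count_pdf_pages(tmp_path / "grp_posteriors.pdf") == 2
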