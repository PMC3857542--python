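"""Race simulator: trial coding, staircase tracking, cross-validation
against the analytic likelihood, and the stratified subsampler."""

import numpy as np
import pytest
from scipy import integrate, stats

from stoprace import (
    DesignSpec,
    ExGaussParams,
    RaceParams,
    dataset_from_frame,
    inhibition_function,
    loglik_signal_respond,
    logprob_inhibit,
    simulate_group,
    simulate_participant,
    subsample_dataset,
)

P = RaceParams(go=ExGaussParams(500.0, 50.0, 100.0), stop=ExGaussParams(200.0, 20.0, 50.0))


class TestDesignSpec:
    def test_requires_exactly_one_schedule(self):
        with pytest.raises(ValueError):
            DesignSpec(n_go=10)
        with pytest.raises(ValueError):
            DesignSpec(n_go=10, ssds={200.0: 5}, staircase=(250.0, 50.0, 5))

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            DesignSpec(n_go=-1, ssds={200.0: 5})
        with pytest.raises(ValueError):
            DesignSpec(n_go=1, ssds={-5.0: 5})
        with pytest.raises(ValueError):
            DesignSpec(n_go=1, staircase=(250.0, 0.0, 5))


class TestSimulateParticipant:
    def test_table_coding_is_valid(self):
        rng = np.random.default_rng(1)
        df = simulate_participant(P, DesignSpec(n_go=50, ssds={250.0: 30}), rng)
        ds = dataset_from_frame(df)  # validation would raise on bad coding
        assert ds.n_trials == 80

    def test_degenerate_fast_stop_inhibits_everything(self):
        fast = RaceParams(go=P.go, stop=ExGaussParams(1e-3, 1e-4, 1e-4))
        rng = np.random.default_rng(2)
        df = simulate_participant(fast, DesignSpec(n_go=0, ssds={50.0: 200}), rng)
        assert (df["inhibited"] == 1).all()

    def test_response_rate_matches_analytic_inhibition_function(self):
        rng = np.random.default_rng(3)
        n = 10_000
        ssds = [200.0, 250.0, 300.0, 350.0, 400.0]
        df = simulate_participant(P, DesignSpec(n_go=0, ssds={d: n for d in ssds}), rng)
        rates = [
            float((df[df["ssd"] == d]["inhibited"] == 0).mean()) for d in ssds
        ]
        assert np.all(np.diff(rates) > 0)  # responding more likely at long delays
        analytic = inhibition_function(np.array(ssds), P)
        for r, a in zip(rates, analytic):
            se = np.sqrt(a * (1 - a) / n)
            assert abs(r - a) < 3 * se

    def test_signal_respond_mean_below_go_mean(self):
        rng = np.random.default_rng(4)
        df = simulate_participant(P, DesignSpec(n_go=5000, ssds={250.0: 5000}), rng)
        go_mean = df[df["ss_presented"] == 0]["rt"].mean()
        sr = df[(df["ss_presented"] == 1) & (df["inhibited"] == 0)]["rt"]
        assert sr.mean() < go_mean  # censoring removes the slow tail

    def test_signal_respond_distribution_matches_censored_density(self):
        rng = np.random.default_rng(6)
        ssd = 300.0
        df = simulate_participant(P, DesignSpec(n_go=0, ssds={ssd: 10_000}), rng)
        sr = df[df["inhibited"] == 0]["rt"].to_numpy()
        # normalized censored-density CDF as the one-sample KS reference
        norm = 1.0 - np.exp(logprob_inhibit(ssd, P))

        def cdf(t):
            t = np.atleast_1d(t)
            return np.array(
                [
                    integrate.quad(
                        lambda u: np.exp(loglik_signal_respond(u, ssd, P)), 1e-9, ti,
                        limit=200,
                    )[0]
                    / norm
                    for ti in t
                ]
            )

        stat, pval = stats.kstest(sr, cdf)
        assert pval > 0.01

    def test_staircase_tracks_one_up_one_down(self):
        rng = np.random.default_rng(7)
        step = 50.0
        df = simulate_participant(P, DesignSpec(n_go=0, staircase=(250.0, step, 200)), rng)
        ssd = df["ssd"].to_numpy()
        inh = df["inhibited"].to_numpy()
        for t in range(len(ssd) - 1):
            if inh[t] == 1:
                assert ssd[t + 1] == ssd[t] + step
            else:
                assert ssd[t + 1] == max(step, ssd[t] - step)
        # tracking should hold responding near 50%
        assert 0.3 < (inh == 0).mean() < 0.7

    def test_seeded_reproducibility(self):
        d = DesignSpec(n_go=20, ssds={250.0: 10})
        a = simulate_participant(P, d, np.random.default_rng(42))
        b = simulate_participant(P, d, np.random.default_rng(42))
        assert a.equals(b)

    def test_negative_mass_warning(self):
        bad = RaceParams(go=ExGaussParams(10.0, 50.0, 20.0), stop=P.stop)
        with pytest.warns(UserWarning, match="negative finishing times"):
            simulate_participant(bad, DesignSpec(n_go=200, ssds={50.0: 1}),
                                 np.random.default_rng(8))


class TestSimulateGroup:
    LOC = np.array([500.0, 50.0, 100.0, 200.0, 20.0, 50.0])
    SPREAD = np.array([30.0, 10.0, 20.0, 20.0, 5.0, 10.0])

    def test_subj_idx_populated_and_valid(self):
        rng = np.random.default_rng(9)
        df = simulate_group(self.LOC, self.SPREAD, 5, DesignSpec(n_go=30, ssds={250.0: 20}), rng)
        ds = dataset_from_frame(df)
        assert ds.is_hierarchical and ds.participants == [1, 2, 3, 4, 5]

    def test_tiny_spread_makes_participants_alike(self):
        rng = np.random.default_rng(10)
        df = simulate_group(
            self.LOC, np.full(6, 1e-3), 6, DesignSpec(n_go=400, ssds={250.0: 1}), rng
        )
        means = df[df["ss_presented"] == 0].groupby("subj_idx")["rt"].mean()
        # all participants share essentially the same go distribution
        se = np.sqrt((50.0**2 + 100.0**2) / 400)
        assert means.max() - means.min() < 6 * se

    def test_seeded_reproducibility(self):
        d = DesignSpec(n_go=10, ssds={250.0: 5})
        a = simulate_group(self.LOC, self.SPREAD, 3, d, np.random.default_rng(11))
        b = simulate_group(self.LOC, self.SPREAD, 3, d, np.random.default_rng(11))
        assert a.equals(b)


class TestSubsample:
    def test_returns_150_trials_per_participant(self, sim_dataset):
        sub = subsample_dataset(sim_dataset.frame, seed=1)
        assert len(sub) == 150
        assert (sub["ss_presented"] == 0).sum() == 90
        assert ((sub["ss_presented"] == 1) & (sub["inhibited"] == 0)).sum() == 30
        assert ((sub["ss_presented"] == 1) & (sub["inhibited"] == 1)).sum() == 30

    def test_hierarchical_subsample(self):
        rng = np.random.default_rng(12)
        df = simulate_group(
            TestSimulateGroup.LOC, TestSimulateGroup.SPREAD, 3,
            DesignSpec(n_go=120, staircase=(250.0, 50.0, 80)), rng,
        )
        sub = subsample_dataset(df, seed=2)
        assert len(sub) == 3 * 150
        assert (sub.groupby("subj_idx").size() == 150).all()

    def test_insufficient_stratum_raises(self):
        rng = np.random.default_rng(13)
        df = simulate_participant(P, DesignSpec(n_go=89, ssds={250.0: 100}), rng)
        with pytest.raises(ValueError, match="not enough go"):
            subsample_dataset(df, seed=3)
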