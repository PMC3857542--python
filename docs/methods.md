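# Methods

## The model

Performance in the stop-signal task is modeled as a race between two
independent processes: a *go* process triggered by the primary-task stimulus
and a *stop* process triggered by the stop signal after a delay (SSD).  The
complete race treats both finishing times as random variables.  On a stop
trial with delay `t_d`, a response is emitted iff the go finishing time
`T_go` satisfies `T_go < t_d + T_stop`; otherwise the response is inhibited.

Both finishing-time distributions are ex-Gaussian — the convolution of a
Normal(μ, σ) with an Exponential of mean τ — a flexible, positively skewed
description of response-time data.  The six parameters are (μ_go, σ_go,
τ_go) and (μ_stop, σ_stop, τ_stop); the SSRT distribution has mean
μ_stop + τ_stop and variance σ_stop² + τ_stop².  The ex-Gaussian is used
descriptively: no cognitive interpretation of individual parameters is
assumed.

The likelihood factors over trials:

* go trial with response time `t`:  `f_go(t)`;
* signal-respond trial: `f_go(t) · S_stop(t − t_d)` — the go RT
  distribution censored by the SSRT distribution, with a censoring point
  `t_d + T_stop` that varies from trial to trial;
* successful inhibition:  `P(T_go > t_d + T_stop) = E_T_stop[S_go(t_d + T_stop)]`.

Context independence is assumed exactly: the go distribution is unaffected
by stop-signal presentation.  No trigger-failure mixture, go omissions, or
SSD-dependent SSRT distributions are modeled.

## Numerical choices

**Log-space ex-Gaussian.**  The textbook density contains
`exp(σ²/2τ²)`, which overflows whenever τ ≪ σ.  All evaluation is in log
space with two exact rewrites switched on the sign of
`z = (t−μ)/σ − σ/τ`: a `log_ndtr` form for `z ≥ 0` (the overflowing factor
cancels analytically against the Gaussian tail) and an `erfcx` form for
`z < 0` (no large intermediate at all).  The survivor function uses the
identity `S(t) = Φ(−(t−μ)/σ) + τ f(t)`, a sum of two positive terms
combined with `logaddexp`, so neither tail suffers cancellation.

**Inhibition probability.**  `E[S_go(t_d + T_stop)]` has no closed form.
The reference path integrates `f_stop(u) · S_go(t_d + u)` with adaptive
quadrature (`scipy.integrate.quad`, relative tolerance 1e-10) over
`[μ_stop − 8σ_stop, μ_stop + 8σ_stop + 50τ_stop]`, which covers the stop
distribution's mass far beyond machine relevance; a failure to converge
raises with diagnostics.  Inside MCMC the integral is needed hundreds of
thousands of times, so a fixed 16×16 Gauss–Hermite × Gauss–Laguerre product
rule is used instead, exploiting the exact Normal + Exponential
decomposition `T_stop = μ + σH + τL`.  The rule is deterministic,
vectorizes over delays, and agrees with the adaptive result to about 1e-4
absolute probability in the worst corner tested (1e-9 in typical regimes)
— negligible against posterior uncertainty.  Both routes are validated
against Monte-Carlo race simulation in the test-suite.  The log
probability is floored at `log(1e-300)` so that absurd parameter states
are rejected by the sampler rather than propagating `−inf`.

**Canonical trial ordering.**  Trials are sorted inside the likelihood
container, which makes the floating-point log-likelihood bitwise invariant
to input trial order (the model itself is exchangeable over trials).

## Priors

Individual fits use independent uniform priors.  Defaults, in
milliseconds: μ_go, μ_stop ~ U(1, 2000); σ and τ parameters ~ U(1, 500).
Hierarchical fits draw each participant-level parameter from a
Normal(group location, group spread) truncated to the same bounds — so
individual and hierarchical supports coincide — with uniform hyperpriors:
locations on the individual ranges, spreads on U(0.01, 500) ms.  The
truncation constant is always included, since it depends on the sampled
hyperparameters.  These ranges are weakly informative: they span plausible
human RTs without constraining well-identified posteriors, and a test
verifies that doubling the ranges leaves a large-sample posterior
essentially unchanged.  Every bound is configurable through a YAML file
(`scale: 0.001` adapts the defaults for data in seconds), and the package
is otherwise unit-agnostic.

## Sampling

Start values are the maximum a-posteriori estimates found by bounded
L-BFGS-B from a moment-based heuristic plus four jittered restarts (three
per participant in hierarchical fits, where group locations and spreads
are initialized from the across-participant mean and SD of the individual
optima).  If every start fails the prior midpoint is used with a warning.

Sampling is Metropolis-within-Gibbs: each sweep updates every scalar
parameter in turn with a Gaussian random-walk proposal accepted by the
Metropolis rule on its full conditional.  Hierarchical sweeps update the
six parameters of each participant, then the six group locations, then the
six group spreads.  Proposal SDs start at 2% of each prior range and are
adapted toward 0.44 acceptance by Robbins–Monro recursion (step
`(sweep+1)^-0.6`) during burn-in only; they are frozen afterwards so the
post-burn-in kernel satisfies detailed balance.  Chain `k` uses seed
`seed + k` and starts from the MAP estimate plus uniform jitter of ±5% of
the prior range (chain 0 starts at the MAP exactly), so chains are
independent, reproducible, and identical whether run sequentially or in
parallel (parallelism is chain-level only, via joblib).

Retention follows `floor((samples − burn_in)/thin)` per chain: every
`thin`-th post-burn-in sweep is kept.  The deviance −2·log-likelihood of
the retained state is stored alongside each draw (summed over participants
in hierarchical fits) and can be written per chain for DIC computation
(`pD = mean deviance − deviance at the posterior mean`).

## Diagnostics and model checks

R-hat is the classic Gelman–Rubin factor (no rank-normalization or
chain-splitting); below ~1.1 is taken as converged, and the remedy for
larger values is more samples, longer burn-in and heavier thinning.
Summaries report the mean, SD and 2.5/25/50/75/97.5 percentiles (type-7
linear interpolation) of the pooled draws; the go and SSRT distribution
mean and SD are computed draw-wise (μ+τ, √(σ²+τ²)) and then summarized,
not recombined from parameter summaries.

Posterior-predictive checks use the per-SSD median signal-respond RT.  For
every delay with at least one observed signal-respond RT, 1000 parameter
vectors (default) are resampled from the pooled posterior, that delay's
total stop-trial count is re-simulated per vector, and the one-sided
p-value is the fraction of replicates whose predicted median is *strictly*
greater than the observed median (ties count as "not greater", which
matters for millisecond-resolution data); two-sided values are
`2·min(p, 1−p)`.  Replicates in which every simulated race is inhibited at
a delay carry no median; they are dropped from that delay's denominator
rather than redrawn (redrawing would bias toward responding), and the
effective count is reported.  Even-count medians average the two central
order statistics.  A reporting filter (`min_sr_per_ssd`) restricts the
table to delays with enough observed signal-respond RTs (≥10 is a sensible
screen) without affecting the computation.  Checks are always made at the
participant level, also in hierarchical fits.

## The simulator

The synthetic-data generator emulates a standard stop-signal session: go
trials drawn from the go distribution, and stop trials raced trial by
trial, with delays either fixed (a list of delays with counts, as in
yoked/fixed-SSD designs) or tracked by the common 1-up/1-down staircase
(delay +step after a successful stop, −step after a response, floored at
one step).  Negative finishing-time draws are rejected and redrawn — the
likelihood places no such constraint, a documented divergence that is
negligible (< 1e-6 rejection mass) at realistic parameters; a warning
fires if the rejection rate exceeds 1%.  Group data draw participant
parameter vectors from the same truncated-Normal group model the
hierarchical prior assumes.  A stratified subsampler (default 90 go / 30
signal-respond / 30 inhibitions = 150 trials per participant) supports
scarce-data experiments.

The generator does not emulate go omissions, trigger failures, RT
contaminants, practice/fatigue drift, or SSD-dependent stopping, so
passing recovery and calibration tests demonstrates correctness of the
estimator under the model's own assumptions — not robustness to the ways
real data violate them.

## Reference study conditions and test problem sizes

The synthetic reference condition is one participant with 720 go trials
and 480 stop trials spread evenly over delays {200, 250, 300, 350, 400} ms
at parameters go = (500, 50, 100) ms and stop = (200, 20, 50) ms, i.e. a
mean SSRT of 250 ms; hierarchical conditions use 20 participants with
group spreads (30, 10, 20, 20, 5, 10) ms and 150 trials each.  The
test-suite's recovery study runs 20 seeded replicates of the reference
condition with 3 chains of 6000 samples (2000 burn-in, thinning 4) and
requires 95% credible intervals to cover at least 5 of 6 true parameters
in ≥90% of replicates; the hierarchical comparison requires narrower
participant-level stop-parameter intervals than individual fits of the
same data in ≥80% of cells, plus shrinkage of participant medians toward
the group mean.  These chain lengths are the package's chosen compromise
for routine verification; production analyses of real data should use
longer chains (e.g. 3 × 36000, burn-in 12000, thinning 12) and confirm
R-hat < 1.1.

## Known limitations

* σ_stop is weakly identified even at 480 stop trials; expect wide
  posteriors and prior sensitivity for that parameter specifically.
* The uniform priors are a documented default, not a canonical choice;
  analyses in other units must rescale them.
* Two-sided posterior predictive p-values assume an approximately
  symmetric test-statistic distribution; with few signal-respond RTs per
  delay the predicted-median distribution is discrete and unstable, and
  p-values there should be read with caution.
* DIC is reported from the deviance trace without alternatives (no WAIC /
  LOO).
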