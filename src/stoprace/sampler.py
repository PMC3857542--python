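"""MAP initialization and Metropolis-within-Gibbs sampling.

Each chain sweeps over the scalar parameters in a fixed order, updating each
with a Gaussian random-walk proposal accepted by the Metropolis rule on its
full conditional.  Proposal standard deviations are adapted toward an
acceptance rate of 0.44 by Robbins-Monro recursion during burn-in only, and
frozen afterwards so the post-burn-in kernel satisfies detailed balance.

Chain ``k`` uses the independent seed ``settings.seed + k`` and starts from
the MAP estimate plus seeded jitter (5% of the prior range), so chains run
concurrently produce draws identical to sequential execution.

The kernel is generic over a small model interface (``init_cache`` /
``delta`` / ``commit`` / ``deviance``); concrete models cover the individual
posterior, the hierarchical posterior, and arbitrary closed-form targets
used by the correctness tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from . import race
from .priors import HierarchicalState, PriorSpec, truncnorm_logpdf
from .race import PARAM_NAMES, RaceParams, TrialArrays, _loglik_theta

__all__ = [
    "MCMCSettings",
    "PosteriorChains",
    "map_start",
    "run_chains",
    "sample_target",
]

log = logging.getLogger(__name__)

_ACCEPT_TARGET = 0.44  # optimal-ish for scalar random-walk updates


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-management settings.

    ``retained`` per chain is ``floor((n_samples - burn_in) / thin)``: with
    a thinning factor of 12 only every 12th post-burn-in sweep is kept.
    """

    n_chains: int = 3
    n_samples: int = 36000
    burn_in: int = 12000
    thin: int = 12
    seed: int = 0
    n_cores: int = 1
    estimates_for: str = "all"  # "all" or "group"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= self.burn_in < self.n_samples):
            raise ValueError("require 0 <= burn_in < n_samples")
        if self.retained < 1:
            raise ValueError("settings retain no draws")
        if self.estimates_for not in ("all", "group"):
            raise ValueError("estimates_for must be 'all' or 'group'")

    @property
    def retained(self) -> int:
        return (self.n_samples - self.burn_in) // self.thin


@dataclass
class PosteriorChains:
    """Retained draws per chain, plus deviance traces and bookkeeping."""

    param_names: list
    chains: list  # one (retained, d) array per chain
    deviance: list  # one (retained,) array per chain (may hold NaN)
    settings: MCMCSettings
    acceptance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {c.shape for c in self.chains}
        if len(lengths) > 1:
            raise ValueError("chains differ in shape")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained(self) -> int:
        return self.chains[0].shape[0]

    def pooled(self) -> np.ndarray:
        return np.vstack(self.chains)

    def pooled_deviance(self) -> np.ndarray:
        return np.concatenate(self.deviance)

    def frame(self, k: int):
        import pandas as pd

        return pd.DataFrame(self.chains[k], columns=self.param_names)

    def pooled_frame(self):
        import pandas as pd

        return pd.DataFrame(self.pooled(), columns=self.param_names)

    def column(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.pooled()[:, j]


# ---------------------------------------------------------------------------
# model objects for the generic kernel
# ---------------------------------------------------------------------------


class _IndividualModel:
    """Posterior of one participant: race likelihood x uniform priors."""

    def __init__(self, arr: TrialArrays, spec: PriorSpec):
        self.arr = arr
        self.spec = spec
        self.lo = spec.lowers()
        self.hi = spec.uppers()
        self.names = list(PARAM_NAMES)
        self.dim = 6

    def logpost(self, x: np.ndarray) -> float:
        if np.any(x <= self.lo) or np.any(x >= self.hi):
            return -np.inf
        return _loglik_theta(self.arr, x)  # flat prior constant dropped

    def init_cache(self, x: np.ndarray) -> dict:
        return {"terms": list(race._loglik_terms(self.arr, x))}

    def delta(self, x, i, new, cache):
        if not (self.lo[i] < new < self.hi[i]):
            return -np.inf, None
        t_go, t_stop, t_inh = cache["terms"]
        old = x[i]
        x[i] = new
        # a scalar update touches either the go-only or the stop-only term,
        # never both; the inhibition term depends on the full vector
        if i < 3:
            t_go_new, t_stop_new = race._term_go(self.arr, x), t_stop
        else:
            t_go_new, t_stop_new = t_go, race._term_stop(self.arr, x)
        t_inh_new = race._term_inhibit(self.arr, x)
        x[i] = old
        lr = (t_go_new + t_stop_new + t_inh_new) - (t_go + t_stop + t_inh)
        return lr, [t_go_new, t_stop_new, t_inh_new]

    def commit(self, cache, upd) -> None:
        cache["terms"] = upd

    def deviance(self, x, cache) -> float:
        return -2.0 * sum(cache["terms"])


class _HierarchicalModel:
    """Joint posterior over participant parameters and group hypers.

    Parameter vector layout: 6 per participant (participants first, in data
    order), then the 6 group locations, then the 6 group spreads.
    """

    def __init__(self, arrs: Sequence[TrialArrays], labels, spec: PriorSpec):
        self.arrs = list(arrs)
        self.labels = list(labels)
        self.spec = spec
        self.S = len(self.arrs)
        self.dim = 6 * self.S + 12
        self.lo = spec.lowers()
        self.hi = spec.uppers()
        self.loc_lo, self.loc_hi = spec.lowers("loc_bounds"), spec.uppers("loc_bounds")
        self.sp_lo, self.sp_hi = spec.lowers("spread_bounds"), spec.uppers("spread_bounds")
        self.names = [
            f"{p}_subj_{lab}" for lab in self.labels for p in PARAM_NAMES
        ] + [f"{p}_group_mean" for p in PARAM_NAMES] + [
            f"{p}_group_sd" for p in PARAM_NAMES
        ]

    # -- vector layout helpers ---------------------------------------------
    def _subj_view(self, x, s):
        return x[6 * s : 6 * s + 6]

    def _loc(self, x):
        return x[6 * self.S : 6 * self.S + 6]

    def _spread(self, x):
        return x[6 * self.S + 6 :]

    def pack(self, state: HierarchicalState) -> np.ndarray:
        return np.concatenate([state.subj.ravel(), state.loc, state.spread])

    def init_cache(self, x) -> dict:
        terms = np.array(
            [race._loglik_terms(a, self._subj_view(x, s)) for s, a in enumerate(self.arrs)]
        )
        loc, spread = self._loc(x), self._spread(x)
        tn = np.empty((self.S, 6))
        for j in range(6):
            tn[:, j] = truncnorm_logpdf(
                x[j : 6 * self.S : 6], float(loc[j]), float(spread[j]), float(self.lo[j]), float(self.hi[j])
            )
        return {"terms": terms, "tn": tn, "colsum": tn.sum(axis=0)}

    def delta(self, x, i, new, cache):
        S = self.S
        if i < 6 * S:  # participant-level parameter
            s, j = divmod(i, 6)
            if not (self.lo[j] < new < self.hi[j]):
                return -np.inf, None
            loc, spread = self._loc(x), self._spread(x)
            tn_new = truncnorm_logpdf(
                new, float(loc[j]), float(spread[j]), float(self.lo[j]), float(self.hi[j])
            )
            old = x[i]
            x[i] = new
            sub = self._subj_view(x, s)
            t_go, t_stop, t_inh = cache["terms"][s]
            if j < 3:
                t_go = race._term_go(self.arrs[s], sub)
            else:
                t_stop = race._term_stop(self.arrs[s], sub)
            t_inh = race._term_inhibit(self.arrs[s], sub)
            x[i] = old
            new_terms = (t_go, t_stop, t_inh)
            lr = (sum(new_terms) - cache["terms"][s].sum()) + (tn_new - cache["tn"][s, j])
            return lr, ("subj", s, j, new_terms, tn_new)
        j = i - 6 * S
        if j < 6:  # group location j
            if not (self.loc_lo[j] < new < self.loc_hi[j]):
                return -np.inf, None
            spread = self._spread(x)
            col = truncnorm_logpdf(
                x[j : 6 * S : 6], float(new), float(spread[j]), float(self.lo[j]), float(self.hi[j])
            )
            return float(col.sum() - cache["colsum"][j]), ("hyper", j, col)
        j -= 6  # group spread j
        if not (self.sp_lo[j] < new < self.sp_hi[j]):
            return -np.inf, None
        loc = self._loc(x)
        col = truncnorm_logpdf(
            x[j : 6 * S : 6], float(loc[j]), float(new), float(self.lo[j]), float(self.hi[j])
        )
        return float(col.sum() - cache["colsum"][j]), ("hyper", j, col)

    def commit(self, cache, upd) -> None:
        if upd[0] == "subj":
            _, s, j, new_terms, tn_new = upd
            cache["colsum"][j] += tn_new - cache["tn"][s, j]
            cache["terms"][s] = new_terms
            cache["tn"][s, j] = tn_new
        else:
            _, j, col = upd
            cache["tn"][:, j] = col
            cache["colsum"][j] = col.sum()

    def deviance(self, x, cache) -> float:
        return -2.0 * float(cache["terms"].sum())


class _GenericModel:
    """Arbitrary log-density target; used to verify sampler correctness
    against closed-form distributions."""

    def __init__(self, logp: Callable, dim: int, names=None, deviance_fn=None):
        self.logp = logp
        self.dim = dim
        self.names = list(names) if names is not None else [f"x{i}" for i in range(dim)]
        self.deviance_fn = deviance_fn

    def init_cache(self, x) -> dict:
        return {"lp": float(self.logp(x))}

    def delta(self, x, i, new, cache):
        old = x[i]
        x[i] = new
        lp_new = float(self.logp(x))
        x[i] = old
        return lp_new - cache["lp"], {"lp": lp_new}

    def commit(self, cache, upd) -> None:
        cache["lp"] = upd["lp"]

    def deviance(self, x, cache) -> float:
        if self.deviance_fn is None:
            return np.nan
        return float(self.deviance_fn(x))


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------


def _run_single_chain(model, x0, settings: MCMCSettings, chain_index: int,
                      init_scales=None, progress: bool = False):
    rng = np.random.default_rng(settings.seed + chain_index)
    x = np.array(x0, dtype=float)
    d = model.dim
    cache = model.init_cache(x)
    scales = (
        np.array(init_scales, dtype=float)
        if init_scales is not None
        else 0.1 * np.abs(x) + 1e-2
    )
    n_ret = settings.retained
    draws = np.empty((n_ret, d))
    dev = np.empty(n_ret)
    acc = np.zeros(d)
    r = 0
    report_every = max(1, settings.n_samples // 20)
    for sweep in range(settings.n_samples):
        adapt = sweep < settings.burn_in
        gamma = (sweep + 1) ** -0.6 if adapt else 0.0
        for i in range(d):
            new = x[i] + scales[i] * rng.standard_normal()
            lr, upd = model.delta(x, i, new, cache)
            accept = lr >= 0.0 or np.log(rng.random()) < lr
            if accept:
                x[i] = new
                model.commit(cache, upd)
            if adapt:
                scales[i] *= np.exp(gamma * ((1.0 if accept else 0.0) - _ACCEPT_TARGET))
            else:
                acc[i] += accept
        if not adapt and (sweep - settings.burn_in + 1) % settings.thin == 0:
            draws[r] = x
            dev[r] = model.deviance(x, cache)
            r += 1
        if progress and (sweep + 1) % report_every == 0:
            log.info("chain %d: %d/%d sweeps", chain_index + 1, sweep + 1, settings.n_samples)
    n_post = max(1, settings.n_samples - settings.burn_in)
    return draws[:r], dev[:r], acc / n_post


def _run_all_chains(model, starts, settings: MCMCSettings, init_scales=None,
                    progress: bool = False) -> PosteriorChains:
    args = [
        (model, starts[k], settings, k, init_scales, progress and k == 0)
        for k in range(settings.n_chains)
    ]
    if settings.n_cores > 1 and settings.n_chains > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=min(settings.n_cores, settings.n_chains))(
            delayed(_run_single_chain)(*a) for a in args
        )
    else:
        results = [_run_single_chain(*a) for a in args]
    return PosteriorChains(
        param_names=list(model.names),
        chains=[r[0] for r in results],
        deviance=[r[1] for r in results],
        settings=settings,
        acceptance=[r[2] for r in results],
    )


# ---------------------------------------------------------------------------
# MAP initialization
# ---------------------------------------------------------------------------


def _moment_start(arr: TrialArrays, spec: PriorSpec) -> np.ndarray:
    """Crude moment-based starting point for the optimizer."""
    lo, hi = spec.lowers(), spec.uppers()
    rts = arr._resp_rt
    m = float(np.mean(rts)) if rts.size else float(np.mean(spec.midpoint()[:1]))
    s = float(np.std(rts)) if rts.size > 1 else 0.2 * m
    s = max(s, 1e-3)
    tau0 = 0.6 * s
    sigma0 = max(np.sqrt(max(s**2 - tau0**2, (0.05 * s) ** 2)), 1e-3)
    mu0 = m - tau0
    start = np.array([mu0, sigma0, tau0, 0.5 * mu0, sigma0, 0.5 * tau0])
    eps = 1e-3 * (hi - lo)
    return np.clip(start, lo + eps, hi - eps)


def _optimize_individual(arr: TrialArrays, spec: PriorSpec, rng, n_starts: int = 5):
    lo, hi = spec.lowers(), spec.uppers()
    eps = 1e-4 * (hi - lo)
    bnds = list(zip(lo + eps, hi - eps))

    def negpost(x):
        v = _loglik_theta(arr, x)
        return -v if np.isfinite(v) else 1e12

    base = _moment_start(arr, spec)
    starts = [base]
    for _ in range(n_starts - 1):
        jit = base + rng.uniform(-0.1, 0.1, size=6) * (hi - lo)
        starts.append(np.clip(jit, lo + eps, hi - eps))
    best_x, best_f = None, np.inf
    for s in starts:
        try:
            res = optimize.minimize(negpost, s, method="L-BFGS-B", bounds=bnds)
        except Exception:  # pragma: no cover - optimizer hiccup
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = np.asarray(res.x), float(res.fun)
    if best_x is None or not np.isfinite(best_f) or best_f >= 1e12:
        log.warning("MAP optimization failed; falling back to prior midpoint")
        best_x = spec.midpoint()
    return np.clip(best_x, lo + eps, hi - eps)


def map_start(data, spec: Optional[PriorSpec] = None, seed: int = 0):
    """Maximum a-posteriori start values via bounded multi-start optimization.

    Returns :class:`RaceParams` for individual data and
    :class:`HierarchicalState` for hierarchical data.  Deterministic under a
    fixed seed; falls back to the prior midpoint if every start fails.
    """
    spec = spec or PriorSpec.default()
    rng = np.random.default_rng(seed)
    if getattr(data, "is_hierarchical", False):
        subj = []
        for lab in data.participants:
            arr = data.participant_arrays(lab)
            subj.append(_optimize_individual(arr, spec, rng, n_starts=3))
        subj = np.array(subj)
        loc = subj.mean(axis=0)
        spread = subj.std(axis=0, ddof=1) if len(subj) > 1 else np.full(6, 1.0)
        slo, shi = spec.lowers("spread_bounds"), spec.uppers("spread_bounds")
        eps = 1e-3 * (shi - slo)
        spread = np.clip(spread, slo + eps, shi - eps)
        llo, lhi = spec.lowers("loc_bounds"), spec.uppers("loc_bounds")
        loc = np.clip(loc, llo + 1e-3 * (lhi - llo), lhi - 1e-3 * (lhi - llo))
        return HierarchicalState(subj=subj, loc=loc, spread=spread)
    arr = race._coerce_arrays(data) if not isinstance(data, TrialArrays) else data
    theta = _optimize_individual(arr, spec, rng)
    return RaceParams.from_array(theta)


# ---------------------------------------------------------------------------
# top-level sampling entry points
# ---------------------------------------------------------------------------


def _jittered_starts(x_map, lo, hi, settings: MCMCSettings):
    """MAP start for chain 0; MAP plus seeded 5%-of-range jitter after."""
    span = 0.05 * (hi - lo)
    eps = 1e-4 * (hi - lo)
    starts = [np.clip(x_map, lo + eps, hi - eps)]
    for k in range(1, settings.n_chains):
        rng = np.random.default_rng(settings.seed + 100_000 + k)
        s = x_map + rng.uniform(-1.0, 1.0, size=len(x_map)) * span
        starts.append(np.clip(s, lo + eps, hi - eps))
    return starts


def run_chains(data, spec: Optional[PriorSpec] = None,
               settings: Optional[MCMCSettings] = None,
               start=None, progress: bool = False) -> PosteriorChains:
    """Sample the individual or hierarchical posterior for ``data``.

    The model structure is chosen automatically: datasets carrying a
    participant column are fit hierarchically, others individually.
    ``start`` overrides MAP initialization (a RaceParams or
    HierarchicalState).
    """
    spec = spec or PriorSpec.default()
    settings = settings or MCMCSettings()
    hierarchical = getattr(data, "is_hierarchical", False)
    if hierarchical:
        labels = list(data.participants)
        arrs = [data.participant_arrays(lab) for lab in labels]
        model = _HierarchicalModel(arrs, labels, spec)
        state = start if start is not None else map_start(data, spec, seed=settings.seed)
        x_map = model.pack(state)
        lo = np.concatenate(
            [np.tile(spec.lowers(), model.S), spec.lowers("loc_bounds"), spec.lowers("spread_bounds")]
        )
        hi = np.concatenate(
            [np.tile(spec.uppers(), model.S), spec.uppers("loc_bounds"), spec.uppers("spread_bounds")]
        )
    else:
        arr = race._coerce_arrays(data)
        model = _IndividualModel(arr, spec)
        p = start if start is not None else map_start(arr, spec, seed=settings.seed)
        x_map = p.to_array() if isinstance(p, RaceParams) else np.asarray(p, dtype=float)
        lo, hi = spec.lowers(), spec.uppers()
    starts = _jittered_starts(x_map, lo, hi, settings)
    cache0 = model.init_cache(starts[0])
    if not np.isfinite(model.deviance(starts[0], cache0)) and not hierarchical:
        raise RuntimeError("non-finite posterior at the starting values")
    init_scales = 0.02 * (hi - lo)
    return _run_all_chains(model, starts, settings, init_scales=init_scales, progress=progress)


def sample_target(logp: Callable, x0, settings: MCMCSettings, names=None,
                  deviance_fn=None, init_scales=None) -> PosteriorChains:
    """Run the Metropolis-within-Gibbs kernel on an arbitrary log-density.

    Exposed so the sampling machinery (retention arithmetic, adaptation,
    seeding) can be verified on targets with known closed forms.
    """
    x0 = np.asarray(x0, dtype=float)
    model = _GenericModel(logp, dim=x0.size, names=names, deviance_fn=deviance_fn)
    starts = [x0.copy() for _ in range(settings.n_chains)]
    for k in range(1, settings.n_chains):
        rng = np.random.default_rng(settings.seed + 100_000 + k)
        starts[k] = x0 + rng.normal(scale=0.1 * (np.abs(x0) + 1.0))
    return _run_all_chains(model, starts, settings, init_scales=init_scales)


def deviance_trace(chains: PosteriorChains, data, spec=None) -> list:
    """Recompute the per-chain deviance vectors from the retained draws.

    For hierarchical chains the deviance sums the participant
    log-likelihoods.  Matches the trace stored during sampling; exists so
    the stored values can be verified independently.
    """
    hierarchical = getattr(data, "is_hierarchical", False)
    out = []
    if hierarchical:
        labels = list(data.participants)
        arrs = {lab: data.participant_arrays(lab) for lab in labels}
        for ch in chains.chains:
            dev = np.empty(ch.shape[0])
            for r in range(ch.shape[0]):
                total = 0.0
                for s, lab in enumerate(labels):
                    total += _loglik_theta(arrs[lab], ch[r, 6 * s : 6 * s + 6])
                dev[r] = -2.0 * total
            out.append(dev)
    else:
        arr = race._coerce_arrays(data)
        for ch in chains.chains:
            out.append(np.array([-2.0 * _loglik_theta(arr, ch[r]) for r in range(ch.shape[0])]))
    return out
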