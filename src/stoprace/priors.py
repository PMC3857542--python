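"""Prior specification for individual and hierarchical race-model fits.

Individual fits place independent uniform priors on the six parameters
(mu_go, sigma_go, tau_go, mu_stop, sigma_stop, tau_stop).  Hierarchical fits
draw each participant-level parameter from a Normal(group location, group
spread) truncated to the individual uniform bounds, with uniform hyperpriors
on the locations and spreads.  Posterior inference is insensitive to these
ranges once the data are reasonably diagnostic; all bounds are
user-configurable through a YAML config file, and a run records the spec it
used.

Default bounds are expressed in milliseconds (the unit of typical human RT
data); ``PriorSpec.default(scale=0.001)`` rescales them for seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .race import PARAM_NAMES

__all__ = [
    "PriorSpec",
    "HierarchicalState",
    "log_prior_individual",
    "log_group_model",
    "truncnorm_logpdf",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

_DEFAULT_BOUNDS_MS = {
    "mu_go": (1.0, 2000.0),
    "sigma_go": (1.0, 500.0),
    "tau_go": (1.0, 500.0),
    "mu_stop": (1.0, 2000.0),
    "sigma_stop": (1.0, 500.0),
    "tau_stop": (1.0, 500.0),
}
_DEFAULT_SPREAD_BOUNDS_MS = (0.01, 500.0)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform bounds for the six parameters plus hierarchical hyperpriors.

    ``bounds`` doubles as the truncation interval of the participant-level
    group distributions, so individual and hierarchical fits share the same
    support.
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS_MS))
    loc_bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS_MS))
    spread_bounds: dict = field(
        default_factory=lambda: {k: _DEFAULT_SPREAD_BOUNDS_MS for k in PARAM_NAMES}
    )

    def __post_init__(self) -> None:
        for table, positive in ((self.bounds, False), (self.loc_bounds, False), (self.spread_bounds, True)):
            for name in PARAM_NAMES:
                if name not in table:
                    raise ValueError(f"missing prior bounds for {name}")
                lo, hi = table[name]
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
                if positive and lo <= 0:
                    raise ValueError(f"spread bounds for {name} must be positive")

    # -- array views in canonical parameter order ---------------------------
    def lowers(self, which: str = "bounds") -> np.ndarray:
        return np.array([getattr(self, which)[n][0] for n in PARAM_NAMES])

    def uppers(self, which: str = "bounds") -> np.ndarray:
        return np.array([getattr(self, which)[n][1] for n in PARAM_NAMES])

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lowers() + self.uppers())

    @classmethod
    def default(cls, scale: float = 1.0) -> "PriorSpec":
        """Default bounds; ``scale`` rescales the millisecond defaults
        (0.001 for data recorded in seconds)."""
        sc = float(scale)
        return cls(
            bounds={k: (lo * sc, hi * sc) for k, (lo, hi) in _DEFAULT_BOUNDS_MS.items()},
            loc_bounds={k: (lo * sc, hi * sc) for k, (lo, hi) in _DEFAULT_BOUNDS_MS.items()},
            spread_bounds={
                k: (_DEFAULT_SPREAD_BOUNDS_MS[0] * sc, _DEFAULT_SPREAD_BOUNDS_MS[1] * sc)
                for k in PARAM_NAMES
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        """Load bounds from a YAML file.

        Recognized keys: ``scale`` (applied to defaults first), then
        ``bounds``, ``loc_bounds``, ``spread_bounds`` mapping parameter
        names to ``[lower, upper]`` pairs overriding the defaults.
        """
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        base = cls.default(scale=cfg.get("scale", 1.0))
        tables = {
            "bounds": dict(base.bounds),
            "loc_bounds": dict(base.loc_bounds),
            "spread_bounds": dict(base.spread_bounds),
        }
        for key, table in tables.items():
            for name, pair in (cfg.get(key) or {}).items():
                if name not in PARAM_NAMES:
                    raise ValueError(f"unknown parameter {name!r} in {key}")
                table[name] = (float(pair[0]), float(pair[1]))
        return cls(**tables)

    def sample_individual(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.lowers(), self.uppers()
        return rng.uniform(lo, hi)


@dataclass
class HierarchicalState:
    """Participant-level parameters plus group locations and spreads."""

    subj: np.ndarray  # (n_participants, 6)
    loc: np.ndarray  # (6,)
    spread: np.ndarray  # (6,)

    def __post_init__(self) -> None:
        self.subj = np.atleast_2d(np.asarray(self.subj, dtype=float))
        self.loc = np.asarray(self.loc, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if self.subj.shape[1] != 6 or self.loc.shape != (6,) or self.spread.shape != (6,):
            raise ValueError("inconsistent hierarchical state shapes")

    @property
    def n_participants(self) -> int:
        return self.subj.shape[0]


def _log_ndtr_diff(beta: float, alpha: float) -> float:
    """log(Phi(beta) - Phi(alpha)) without cancellation, for beta > alpha."""
    if beta <= 0.0:  # both in the lower tail
        lb = special.log_ndtr(beta)
        la = special.log_ndtr(alpha)
        return float(lb + np.log1p(-np.exp(la - lb)))
    if alpha >= 0.0:  # both in the upper tail
        la = special.log_ndtr(-alpha)
        lb = special.log_ndtr(-beta)
        return float(la + np.log1p(-np.exp(lb - la)))
    # straddles zero: the difference is >= Phi(beta) - 1/2, safe directly
    return float(np.log(special.ndtr(beta) - special.ndtr(alpha)))


def truncnorm_logpdf(x, loc: float, scale: float, lo: float, hi: float):
    """Log-density of a Normal(loc, scale) truncated to [lo, hi].

    The normalization constant is included: it depends on (loc, scale) and
    cannot be dropped when those are themselves sampled.
    """
    if not (scale > 0.0):
        raise ValueError(f"scale must be > 0, got {scale}")
    if not (lo < hi):
        raise ValueError("invalid truncation interval")
    x = np.asarray(x, dtype=float)
    logz = _log_ndtr_diff((hi - loc) / scale, (lo - loc) / scale)
    z = (x - loc) / scale
    out = -0.5 * z * z - _LOG_SQRT_2PI - math.log(scale) - logz
    out = np.where((x < lo) | (x > hi), -np.inf, out)
    return float(out[()]) if out.ndim == 0 else out


def log_prior_individual(theta, spec: PriorSpec) -> float:
    """Sum of independent uniform log-densities; -inf outside the support."""
    t = np.asarray(theta, dtype=float)
    lo, hi = spec.lowers(), spec.uppers()
    if np.any(t <= lo) or np.any(t >= hi):
        return -np.inf
    return float(-np.sum(np.log(hi - lo)))


def log_group_model(state: HierarchicalState, spec: PriorSpec) -> float:
    """Hierarchical log-density: truncated-Normal participant terms plus
    uniform hyperprior terms for the group locations and spreads."""
    lo, hi = spec.lowers(), spec.uppers()
    llo, lhi = spec.lowers("loc_bounds"), spec.uppers("loc_bounds")
    slo, shi = spec.lowers("spread_bounds"), spec.uppers("spread_bounds")
    if np.any(state.loc <= llo) or np.any(state.loc >= lhi):
        return -np.inf
    if np.any(state.spread <= slo) or np.any(state.spread >= shi):
        return -np.inf
    total = float(-np.sum(np.log(lhi - llo)) - np.sum(np.log(shi - slo)))
    for j in range(6):
        terms = truncnorm_logpdf(
            state.subj[:, j], float(state.loc[j]), float(state.spread[j]), float(lo[j]), float(hi[j])
        )
        s = float(np.sum(terms))
        if not np.isfinite(s):
            return -np.inf
        total += s
    return total
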