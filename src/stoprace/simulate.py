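"""Race-model simulator: synthetic stop-signal datasets with known truth.

Each trial races a go finishing time against SSD + SSRT, both ex-Gaussian.
A go RT longer than SSD + SSRT is successfully inhibited; a shorter one
escapes inhibition and is recorded as a signal-respond RT.  Stop-signal
delays follow either a fixed list with per-delay trial counts or a
1-up/1-down staircase (SSD moves up one step after a successful stop, down
one step after a response), the tracking rule most experiments use.

Negative finishing-time draws (possible because the Gaussian component has
full real support) are rejected and redrawn; a warning is raised when the
rejection rate exceeds 1%, since such parameters place non-physiological
mass below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exgauss import ExGaussParams
from .race import PARAM_NAMES, RaceParams

__all__ = [
    "DesignSpec",
    "simulate_participant",
    "simulate_group",
    "subsample_dataset",
]

SENTINEL = -999

COLUMNS = ["ss_presented", "inhibited", "ssd", "rt"]


@dataclass(frozen=True)
class DesignSpec:
    """Trial counts and stop-signal delay schedule for one participant.

    Exactly one of ``ssds`` (mapping delay -> trial count) or ``staircase``
    ``(start, step, n_stop)`` must be given.
    """

    n_go: int
    ssds: Optional[Mapping[float, int]] = None
    staircase: Optional[Tuple[float, float, int]] = None

    def __post_init__(self) -> None:
        if self.n_go < 0:
            raise ValueError("n_go must be >= 0")
        if (self.ssds is None) == (self.staircase is None):
            raise ValueError("specify exactly one of ssds or staircase")
        if self.ssds is not None:
            if not self.ssds or any(d <= 0 or c < 0 for d, c in self.ssds.items()):
                raise ValueError("fixed SSDs must be positive with counts >= 0")
        else:
            start, step, n_stop = self.staircase
            if start <= 0 or step <= 0 or n_stop < 0:
                raise ValueError("staircase requires start > 0, step > 0, n_stop >= 0")

    @property
    def n_stop(self) -> int:
        if self.ssds is not None:
            return int(sum(self.ssds.values()))
        return int(self.staircase[2])


def _draw_positive(p: ExGaussParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ex-Gaussian draws with negative values rejected and redrawn."""
    out = rng.normal(p.mu, p.sigma, size=n) + rng.exponential(p.tau, size=n)
    total = n
    bad = out <= 0
    while bad.any():
        k = int(bad.sum())
        total += k
        out[bad] = rng.normal(p.mu, p.sigma, size=k) + rng.exponential(p.tau, size=k)
        bad = out <= 0
    if n and (total - n) / total > 0.01:
        warnings.warn(
            f"rejected {total - n}/{total} negative finishing times; "
            "parameters imply non-physiological mass below zero",
            stacklevel=2,
        )
    return out


def simulate_participant(p: RaceParams, design: DesignSpec,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one participant's go and stop trials in the table coding.

    Returns a DataFrame with columns ss_presented, inhibited, ssd, rt; the
    sentinel -999 marks inapplicable fields (ssd/rt on go trials, rt on
    inhibited trials).
    """
    rows = []
    go_rt = _draw_positive(p.go, design.n_go, rng)
    for rt in go_rt:
        rows.append((0, SENTINEL, SENTINEL, float(rt)))

    if design.ssds is not None:
        for ssd, count in design.ssds.items():
            g = _draw_positive(p.go, int(count), rng)
            s = _draw_positive(p.stop, int(count), rng)
            inhibited = g > ssd + s
            for gi, ok in zip(g, inhibited):
                if ok:
                    rows.append((1, 1, float(ssd), float(SENTINEL)))
                else:
                    rows.append((1, 0, float(ssd), float(gi)))
    else:
        ssd = float(design.staircase[0])
        step = float(design.staircase[1])
        for _ in range(int(design.staircase[2])):
            g = float(_draw_positive(p.go, 1, rng)[0])
            s = float(_draw_positive(p.stop, 1, rng)[0])
            if g > ssd + s:
                rows.append((1, 1, ssd, float(SENTINEL)))
                ssd = ssd + step
            else:
                rows.append((1, 0, ssd, g))
                ssd = max(step, ssd - step)
    return pd.DataFrame(rows, columns=COLUMNS)


def _truncnorm_draws(loc, spread, lo, hi, size, rng):
    a = (lo - loc) / spread
    b = (hi - loc) / spread
    return stats.truncnorm.rvs(a, b, loc=loc, scale=spread, size=size, random_state=rng)


def simulate_group(loc, spread, n_participants: int, design: DesignSpec,
                   rng: np.random.Generator, bounds: Optional[dict] = None) -> pd.DataFrame:
    """Simulate a hierarchical dataset.

    Participant parameter vectors are drawn from Normal(loc, spread)
    truncated to ``bounds`` (defaults to the default prior bounds), matching
    the hierarchical model's group distributions; a ``subj_idx`` column
    labels participants 1..n.
    """
    from .priors import PriorSpec

    loc = np.asarray(loc, dtype=float)
    spread = np.asarray(spread, dtype=float)
    if loc.shape != (6,) or spread.shape != (6,):
        raise ValueError("loc and spread must have length 6")
    if np.any(spread <= 0):
        raise ValueError("spread must be positive")
    bounds = bounds or PriorSpec.default().bounds
    frames = []
    for s in range(int(n_participants)):
        theta = np.array(
            [
                _truncnorm_draws(loc[j], spread[j], *bounds[PARAM_NAMES[j]], size=1, rng=rng)[0]
                for j in range(6)
            ]
        )
        df = simulate_participant(RaceParams.from_array(theta), design, rng)
        df.insert(0, "subj_idx", s + 1)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def subsample_dataset(frame: pd.DataFrame, n_go: int = 90, n_signal_respond: int = 30,
                      n_inhibit: int = 30, rng: Optional[np.random.Generator] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Stratified random subsample by trial type, per participant.

    Draws ``n_go`` go trials, ``n_signal_respond`` signal-respond trials and
    ``n_inhibit`` successful inhibitions without replacement for each
    participant; raises if any stratum is too small.  The default 90/30/30
    split yields 150 trials per participant.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)

    def take(df: pd.DataFrame) -> pd.DataFrame:
        go = df.index[(df["ss_presented"] == 0)]
        sr = df.index[(df["ss_presented"] == 1) & (df["inhibited"] == 0)]
        inh = df.index[(df["ss_presented"] == 1) & (df["inhibited"] == 1)]
        for idx, need, label in ((go, n_go, "go"), (sr, n_signal_respond, "signal-respond"),
                                 (inh, n_inhibit, "inhibition")):
            if len(idx) < need:
                raise ValueError(
                    f"not enough {label} trials: have {len(idx)}, need {need}"
                )
        keep = np.concatenate(
            [
                rng.choice(go, size=n_go, replace=False),
                rng.choice(sr, size=n_signal_respond, replace=False),
                rng.choice(inh, size=n_inhibit, replace=False),
            ]
        )
        return df.loc[np.sort(keep)]

    if "subj_idx" in frame.columns:
        parts = [take(g) for _, g in frame.groupby("subj_idx", sort=False)]
        return pd.concat(parts, ignore_index=True)
    return take(frame).reset_index(drop=True)
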