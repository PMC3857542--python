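"""Convergence diagnostics, posterior summaries, DIC, and plot output.

R-hat is the classic Gelman-Rubin potential scale reduction factor (no
chain-splitting or rank-normalization): with m chains of n draws,
``W`` the mean within-chain variance and ``B = n * var(chain means)``,

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

Values below about 1.1 indicate converged, well-mixed chains; the remedy
for larger values is longer chains, more burn-in, and heavier thinning.

Summaries report the posterior mean, SD and the 2.5/25/50/75/97.5
percentiles (type-7 linear interpolation); the 2.5-97.5 span is the 95%
credible interval.  Derived rows give the mean and SD of the go and SSRT
distributions, computed draw-wise from mu + tau and sqrt(sigma^2 + tau^2)
and then summarized.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .priors import PriorSpec
from .race import PARAM_NAMES
from .sampler import PosteriorChains

__all__ = ["rhat", "rhat_table", "summarize", "dic", "render_plots"]

QUANTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def rhat(chains: Sequence[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction for one scalar parameter."""
    arrs = [np.asarray(c, dtype=float) for c in chains]
    m = len(arrs)
    if m < 2:
        raise ValueError("rhat requires at least 2 chains")
    n = arrs[0].size
    if n < 2 or any(a.size != n for a in arrs):
        raise ValueError("chains must have equal length >= 2")
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    w = variances.mean()
    if w <= 0:
        raise ValueError("zero within-chain variance")
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat_table(pc: PosteriorChains) -> dict:
    """R-hat per parameter across the chains of a run."""
    out = {}
    for j, name in enumerate(pc.param_names):
        out[name] = rhat([c[:, j] for c in pc.chains])
    return out


def _quantile_row(x: np.ndarray) -> dict:
    row = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0}
    qs = np.percentile(x, QUANTILES)  # type-7 linear interpolation
    for q, v in zip(QUANTILES, qs):
        row[f"q{q:g}"] = float(v)
    return row


def _derived_columns(df: pd.DataFrame) -> dict:
    """Draw-wise derived distribution summaries for every parameter scope.

    Scopes: the bare six-parameter set (individual fit), the group-location
    set (suffix ``_group_mean``), and each participant (suffix
    ``_subj_<label>``).
    """
    out = {}

    def add(suffix: str, outfix: str) -> None:
        names = [f"{p}{suffix}" for p in PARAM_NAMES]
        if all(n in df.columns for n in names):
            mu_g, s_g, t_g, mu_s, s_s, t_s = (df[n].to_numpy() for n in names)
            out[f"mean_go{outfix}"] = mu_g + t_g
            out[f"sd_go{outfix}"] = np.sqrt(s_g**2 + t_g**2)
            out[f"mean_stop{outfix}"] = mu_s + t_s
            out[f"sd_stop{outfix}"] = np.sqrt(s_s**2 + t_s**2)

    add("", "")
    add("_group_mean", "_group")
    labels = sorted(
        {m.group(1) for c in df.columns for m in [re.match(r"mu_go_subj_(.+)$", c)] if m}
    )
    for lab in labels:
        add(f"_subj_{lab}", f"_subj_{lab}")
    return out


def _select_names(names: Iterable[str], estimates_for: str) -> list:
    if estimates_for == "group":
        return [n for n in names if "_group_" in n or "_group" == n[-6:]]
    return list(names)


def summarize(pc: PosteriorChains, include_derived: bool = True,
              estimates_for: str = "all") -> pd.DataFrame:
    """Posterior summary table over the pooled draws of all chains."""
    df = pc.pooled_frame()
    rows, index = [], []
    for name in _select_names(pc.param_names, estimates_for):
        rows.append(_quantile_row(df[name].to_numpy()))
        index.append(name)
    if include_derived:
        derived = _derived_columns(df)
        for name in _select_names(derived.keys(), estimates_for):
            rows.append(_quantile_row(derived[name]))
            index.append(name)
    out = pd.DataFrame(rows, index=pd.Index(index, name="parameter"))
    return out


def dic(deviance: np.ndarray, deviance_at_mean: float) -> tuple:
    """Deviance information criterion.

    ``pD = mean(deviance) - deviance(posterior mean)`` estimates the
    effective number of parameters; ``DIC = mean(deviance) + pD``.
    """
    dev = np.asarray(deviance, dtype=float)
    if dev.size == 0:
        raise ValueError("empty deviance vector")
    dbar = float(dev.mean())
    pd_ = dbar - float(deviance_at_mean)
    return dbar + pd_, pd_


def _prior_overlay(name: str, spec: Optional[PriorSpec]):
    """Uniform prior bounds to overlay for a parameter name, if fixed."""
    if spec is None:
        return None
    if name in spec.bounds:
        return spec.bounds[name]
    m = re.match(r"(.+)_group_mean$", name)
    if m and m.group(1) in spec.loc_bounds:
        return spec.loc_bounds[m.group(1)]
    m = re.match(r"(.+)_group_sd$", name)
    if m and m.group(1) in spec.spread_bounds:
        return spec.spread_bounds[m.group(1)]
    return None  # participant-level conditional priors are not fixed


def render_plots(pc: PosteriorChains, spec: Optional[PriorSpec], basename: str,
                 estimates_for: str = "all") -> list:
    """Write posterior-density and trace-plot PDFs; returns the file paths.

    Posterior pages overlay the (uniform) prior density where it is fixed;
    trace pages draw all chains in distinguishable colors.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    names = _select_names(pc.param_names, estimates_for)
    per_page = 6
    paths = []

    post_path = f"{basename}_posteriors.pdf"
    with PdfPages(post_path) as pdf:
        for i0 in range(0, len(names), per_page):
            page = names[i0 : i0 + per_page]
            fig, axes = plt.subplots(2, 3, figsize=(11, 7))
            for ax, name in zip(axes.ravel(), page):
                x = pc.column(name)
                ax.hist(x, bins=40, density=True, color="0.7")
                b = _prior_overlay(name, spec)
                if b is not None:
                    lo, hi = b
                    ax.hlines(1.0 / (hi - lo), lo, hi, color="k", linestyle=":")
                ax.set_title(name, fontsize=9)
            for ax in axes.ravel()[len(page) :]:
                ax.set_axis_off()
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    paths.append(post_path)

    trace_path = f"{basename}_traces.pdf"
    with PdfPages(trace_path) as pdf:
        for i0 in range(0, len(names), per_page):
            page = names[i0 : i0 + per_page]
            fig, axes = plt.subplots(2, 3, figsize=(11, 7))
            for ax, name in zip(axes.ravel(), page):
                j = pc.param_names.index(name)
                for k, ch in enumerate(pc.chains):
                    ax.plot(ch[:, j], lw=0.5, label=f"chain {k + 1}")
                ax.set_title(name, fontsize=9)
            for ax in axes.ravel()[len(page) :]:
                ax.set_axis_off()
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    paths.append(trace_path)
    return paths
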