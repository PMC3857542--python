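"""Posterior-predictive goodness-of-fit checks on median signal-respond RTs.

For each stop-signal delay with at least one observed signal-respond RT,
parameter vectors are drawn from the joint posterior (rows of the pooled
chains, with replacement), that delay's full number of stop trials is
re-simulated from the race model for each draw, and the median of the
predicted signal-respond RTs is compared with the observed median.  The
one-sided posterior predictive p-value is the fraction of replicates whose
predicted median is strictly greater than the observed one (ties count as
"not greater"); the two-sided value is ``2 * min(p, 1 - p)``.  Replicates in
which every simulated race at a delay ends in inhibition contribute no
median and are dropped from that delay's denominator; the surviving count is
reported as ``n_effective_replicates``.

p-values near 0 or 1 flag misfit; medians built on only a handful of
observed signal-respond RTs are unstable, so a reporting filter
(``min_sr_per_ssd``) lets users restrict the table to delays with enough
observations (10 is a common screen).  The filter affects reporting only,
never the computation.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .race import PARAM_NAMES

__all__ = ["participant_draws", "run_ppc", "render_violin"]

log = logging.getLogger(__name__)

PPC_COLUMNS = [
    "ssd",
    "n_observed_sr",
    "observed_median",
    "mean_predicted_median",
    "p_one_sided",
    "p_two_sided",
    "n_effective_replicates",
]


def participant_draws(chains, label=None) -> np.ndarray:
    """Pooled (draws, 6) posterior matrix for one participant.

    For individual fits the six base parameters are returned; for
    hierarchical fits the participant-level columns of ``label``.  Model
    checks always run on the participant level, whatever the fit.
    """
    if label is None:
        names = list(PARAM_NAMES)
    else:
        names = [f"{p}_subj_{label}" for p in PARAM_NAMES]
    idx = [chains.param_names.index(n) for n in names]
    return chains.pooled()[:, idx]


def _positive_matrix(mu, sigma, tau, shape, rng) -> np.ndarray:
    """Row-wise ex-Gaussian draws (one parameter vector per row), negatives
    rejected and redrawn as in the trial simulator."""
    x = rng.normal(mu, sigma, size=shape) + rng.exponential(1.0, size=shape) * tau
    bad = x <= 0
    while bad.any():
        k = int(bad.sum())
        rows = np.nonzero(bad)[0]
        x[bad] = (
            rng.normal(np.broadcast_to(mu, shape)[bad], np.broadcast_to(sigma, shape)[bad])
            + rng.exponential(1.0, size=k) * np.broadcast_to(tau, shape)[bad]
        )
        bad = x <= 0
    return x


def run_ppc(arr, chains_or_draws, n_predictions: int = 1000,
            rng: Optional[np.random.Generator] = None, seed: int = 0,
            min_sr_per_ssd: int = 1, label=None):
    """Per-SSD posterior-predictive checks for one participant.

    ``arr`` is the participant's :class:`~stoprace.race.TrialArrays` (or a
    dataset/frame coercible to one); ``chains_or_draws`` is a
    :class:`~stoprace.sampler.PosteriorChains` or a ready (draws, 6) matrix.
    Returns ``(table, predicted)`` where ``predicted`` maps each SSD to its
    vector of predicted medians (NaN for empty replicates).
    """
    from .race import _coerce_arrays

    arr = _coerce_arrays(arr)
    if n_predictions < 1:
        raise ValueError("n_predictions must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    draws = (
        chains_or_draws
        if isinstance(chains_or_draws, np.ndarray)
        else participant_draws(chains_or_draws, label)
    )
    if arr.sr_rt.size == 0:
        log.warning("no signal-respond RTs: nothing to check")
        return pd.DataFrame(columns=PPC_COLUMNS), {}

    # stop-trial count per delay = responded + inhibited at that delay
    sr_ssd, sr_counts = np.unique(arr.sr_ssd, return_counts=True)
    totals = {float(d): int(c) for d, c in zip(sr_ssd, sr_counts)}
    for d, c in zip(arr.inhibit_ssd, arr.inhibit_n):
        if float(d) in totals:
            totals[float(d)] += int(c)

    rows, predicted = [], {}
    for ssd, n_obs in zip(sr_ssd, sr_counts):
        ssd = float(ssd)
        n_trials = totals[ssd]
        obs_median = float(np.median(arr.sr_rt[arr.sr_ssd == ssd]))
        idx = rng.integers(0, draws.shape[0], size=n_predictions)
        th = draws[idx]
        shape = (n_predictions, n_trials)
        go = _positive_matrix(th[:, 0:1], th[:, 1:2], th[:, 2:3], shape, rng)
        ssrt = _positive_matrix(th[:, 3:4], th[:, 4:5], th[:, 5:6], shape, rng)
        responded = go <= ssd + ssrt
        sr = np.where(responded, go, np.nan)
        import warnings as _warnings

        with _warnings.catch_warnings():
            # all-inhibited replicates legitimately produce all-NaN rows
            _warnings.simplefilter("ignore", RuntimeWarning)
            pred_median = np.nanmedian(sr, axis=1)
        valid = ~np.isnan(pred_median)
        n_eff = int(valid.sum())
        if n_eff == 0:
            p_one = np.nan
            p_two = np.nan
            mean_pred = np.nan
        else:
            p_one = float(np.mean(pred_median[valid] > obs_median))
            p_two = 2.0 * min(p_one, 1.0 - p_one)
            mean_pred = float(np.mean(pred_median[valid]))
        predicted[ssd] = pred_median
        rows.append(
            {
                "ssd": ssd,
                "n_observed_sr": int(n_obs),
                "observed_median": obs_median,
                "mean_predicted_median": mean_pred,
                "p_one_sided": p_one,
                "p_two_sided": p_two,
                "n_effective_replicates": n_eff,
            }
        )
    table = pd.DataFrame(rows, columns=PPC_COLUMNS)
    if min_sr_per_ssd > 1:
        table = table[table["n_observed_sr"] >= min_sr_per_ssd].reset_index(drop=True)
    return table, predicted


def render_violin(predicted: dict, observed: dict, path: str) -> Optional[str]:
    """Violin-plot summary of the model checks, one panel per participant.

    ``predicted``: {participant label: {ssd: vector of predicted medians}};
    ``observed``: {participant label: {ssd: observed median}}.  Each panel
    shows per-SSD violins of the predicted medians with a 25-75% box, the
    median of predicted medians (white circle) and the observed median
    (black triangle).  Returns the path, or None when there is nothing to
    plot.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    labels = [lab for lab in predicted if predicted[lab]]
    if not labels:
        log.warning("no qualifying SSDs: violin plot not written")
        return None
    with PdfPages(path) as pdf:
        for lab in labels:
            per_ssd = predicted[lab]
            ssds = sorted(per_ssd)
            data = [np.asarray(per_ssd[d])[~np.isnan(per_ssd[d])] for d in ssds]
            fig, ax = plt.subplots(figsize=(8, 5))
            pos = np.arange(1, len(ssds) + 1)
            keep = [i for i, v in enumerate(data) if v.size > 0]
            if keep:
                ax.violinplot([data[i] for i in keep], positions=pos[keep],
                              showextrema=False)
                for i in keep:
                    q25, q50, q75 = np.percentile(data[i], [25, 50, 75])
                    ax.vlines(pos[i], q25, q75, color="k", lw=4)
                    ax.plot(pos[i], q50, "o", color="white", mec="k", zorder=3)
            for i, d in enumerate(ssds):
                ax.plot(pos[i], observed[lab][d], "^", color="k", ms=9, zorder=4)
            ax.set_xticks(pos)
            ax.set_xticklabels([f"{d:g}" for d in ssds])
            ax.set_xlabel("stop-signal delay")
            ax.set_ylabel("median signal-respond RT")
            title = "model checks" if lab is None else f"model checks: participant {lab}"
            ax.set_title(title)
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    return path
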