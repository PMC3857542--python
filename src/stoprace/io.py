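"""Reading, validating and writing stop-signal CSV files.

Input files are comma-separated with a header row and the columns
``ss_presented``, ``inhibited``, ``ssd``, ``rt`` (plus ``subj_idx`` for
hierarchical data).  The coding follows the convention where ``-999`` marks
an inapplicable field:

=============  =========  =====  ====
trial type     inhibited  ssd    rt
=============  =========  =====  ====
go             -999       -999   >0
signal-respond 0          >0     >0
inhibition     1          >0     -999
=============  =========  =====  ====

Presence of a ``subj_idx`` column decides hierarchical versus individual
analysis.  Result files (per-chain parameter and deviance CSVs, summary
CSV, model-check CSV) are written next to the input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .race import TrialArrays

__all__ = [
    "FormatError",
    "ValidationError",
    "StopSignalDataset",
    "read_dataset",
    "dataset_from_frame",
    "write_dataset",
    "write_chain_files",
    "write_summary_csv",
    "write_ppc_csv",
]

log = logging.getLogger(__name__)

SENTINEL = -999
REQUIRED_COLUMNS = ("ss_presented", "inhibited", "ssd", "rt")


class FormatError(ValueError):
    """The file does not have the expected structure (columns, header)."""


class ValidationError(ValueError):
    """A row violates the trial coding invariants."""


@dataclass
class StopSignalDataset:
    """A validated set of stop-signal trials, individual or hierarchical."""

    frame: pd.DataFrame
    is_hierarchical: bool
    path: Path | None = None
    time_unit: str = "ms"
    participants: list = field(init=False)

    def __post_init__(self) -> None:
        if self.is_hierarchical:
            # first-appearance order
            self.participants = list(dict.fromkeys(self.frame["subj_idx"]))
        else:
            self.participants = [None]

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def participant_frame(self, label) -> pd.DataFrame:
        if not self.is_hierarchical:
            return self.frame
        return self.frame[self.frame["subj_idx"] == label]

    def participant_arrays(self, label) -> TrialArrays:
        return TrialArrays.from_frame(self.participant_frame(label))

    def arrays(self) -> TrialArrays:
        if self.is_hierarchical and len(self.participants) > 1:
            raise ValueError("hierarchical dataset: select a participant first")
        return TrialArrays.from_frame(self.frame)


def _validate_frame(df: pd.DataFrame, hierarchical: bool) -> pd.DataFrame:
    cols = list(REQUIRED_COLUMNS) + (["subj_idx"] if hierarchical else [])
    extra = [c for c in df.columns if c not in cols]
    if extra:
        log.warning("ignoring extra columns: %s", ", ".join(extra))
    df = df[cols].copy()
    if df.empty:
        raise FormatError("file contains a header but no trials")
    for c in cols:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(
                f"row {row}: column {c!r} is blank or non-numeric "
                f"(only the sentinel {SENTINEL} marks missing values)"
            )
        df[c] = col
    ss = df["ss_presented"].to_numpy()
    inh = df["inhibited"].to_numpy()
    ssd = df["ssd"].to_numpy()
    rt = df["rt"].to_numpy()
    if not np.isin(ss, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(ss, (0, 1)))[0]) + 1
        raise ValidationError(f"row {row}: ss_presented must be 0 or 1")
    if not np.isin(inh, (SENTINEL, 0, 1)).all():
        row = int(np.flatnonzero(~np.isin(inh, (SENTINEL, 0, 1)))[0]) + 1
        raise ValidationError(f"row {row}: inhibited must be -999, 0 or 1")
    go = ss == 0
    bad = go & ~((inh == SENTINEL) & (ssd == SENTINEL) & (rt > 0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"row {row}: go trials require inhibited=-999, ssd=-999, rt>0"
        )
    stopped = (ss == 1) & (inh == 1)
    bad = stopped & ~((rt == SENTINEL) & (ssd > 0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"row {row}: inhibited stop trials require rt=-999 and ssd>0"
        )
    responded = (ss == 1) & (inh == 0)
    bad = responded & ~((rt > 0) & (ssd > 0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"row {row}: signal-respond trials require rt>0 and ssd>0"
        )
    groups = df.groupby("subj_idx", sort=False) if hierarchical else [(None, df)]
    for label, g in groups:
        n_go = int((g["ss_presented"] == 0).sum())
        n_stop = int((g["ss_presented"] == 1).sum())
        if n_go < 1 or n_stop < 1:
            who = f"participant {label}" if hierarchical else "dataset"
            raise ValidationError(
                f"{who} needs at least one go and one stop-signal trial "
                f"(found {n_go} go, {n_stop} stop); stop parameters are "
                "unidentifiable otherwise"
            )
    return df


def read_dataset(path) -> StopSignalDataset:
    """Read and validate a stop-signal CSV file.

    The hierarchical flag is set by the presence of a ``subj_idx`` column.
    Raises :class:`FormatError` for structural problems (missing columns,
    empty file) and :class:`ValidationError` for rows violating the coding,
    citing the 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    hierarchical = "subj_idx" in df.columns
    df = _validate_frame(df, hierarchical)
    return StopSignalDataset(frame=df, is_hierarchical=hierarchical, path=path)


def dataset_from_frame(frame: pd.DataFrame, validate: bool = True) -> StopSignalDataset:
    """Wrap an in-memory DataFrame (e.g. simulator output) as a dataset."""
    hierarchical = "subj_idx" in frame.columns
    if validate:
        frame = _validate_frame(frame, hierarchical)
    return StopSignalDataset(frame=frame, is_hierarchical=hierarchical)


def write_dataset(frame: pd.DataFrame, path) -> Path:
    """Write trials to CSV in the table coding (sentinels as integers)."""
    path = Path(path)
    out = frame.copy()
    for c in ("ss_presented", "inhibited"):
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)
    return path


def write_chain_files(chains, basename: str, deviance: bool = False) -> List[Path]:
    """Write one ``<basename>_parameters<k>.csv`` per chain (and optionally
    ``<basename>_deviance<k>.csv``); returns the created paths."""
    if chains.n_chains < 1 or chains.n_retained < 1:
        raise ValueError("need at least one chain with at least one retained draw")
    paths = []
    # %.17g round-trips IEEE doubles exactly through decimal text
    for k in range(chains.n_chains):
        p = Path(f"{basename}_parameters{k + 1}.csv")
        chains.frame(k).to_csv(p, index=False, float_format="%.17g")
        paths.append(p)
    if deviance:
        for k in range(chains.n_chains):
            p = Path(f"{basename}_deviance{k + 1}.csv")
            pd.DataFrame({"deviance": chains.deviance[k]}).to_csv(
                p, index=False, float_format="%.17g"
            )
            paths.append(p)
    return paths


def read_chain_file(path) -> pd.DataFrame:
    """Read a per-chain CSV back with correctly-rounded float parsing, so a
    write/read cycle reproduces the retained draws bit-identically."""
    return pd.read_csv(path, float_precision="round_trip")


def write_summary_csv(table: pd.DataFrame, path) -> Path:
    """Write a posterior summary table (one row per reported quantity)."""
    if table.empty:
        raise ValueError("empty summary table")
    path = Path(path)
    table.to_csv(path, index=True)
    return path


def write_ppc_csv(table: pd.DataFrame, path) -> Path:
    """Write the per-SSD posterior-predictive check table."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
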