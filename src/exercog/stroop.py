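"""Scoring of the modified dual-task Stroop task.

Each subject x condition x timepoint x block cell of trials is summarised
into mean reaction time over correct trials (ms), error rate, and the
inverse efficiency score IES = mean correct RT / (1 - error rate), which
penalises speed-accuracy trade-offs (higher = less efficient).  Measures are
then z-scored against a normalisation pool so that heterogeneous measures
are comparable and change scores are interpretable.

By default the pool is all subjects' *pre-intervention* cells for a given
measure and block, and the resulting (mean, sd) are applied to both
timepoints; post-intervention z-values therefore read as change relative to
the pre-intervention population distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BehavioralSummary", "summarize_cell", "summarize_trials", "zscore_measures"]

CELL_KEYS = ["subject", "condition", "timepoint", "block"]
MEASURES = ["rt", "er", "ies"]


@dataclass
class BehavioralSummary:
    """Scored measures for one cell of trials."""

    mean_rt_correct_ms: float
    error_rate: float
    ies_ms: float
    n_trials: int
    n_correct: int
    undefined_rt: bool = False  # no correct trials in the cell
    infinite_ies: bool = False  # error rate of exactly 1


def summarize_cell(trials: pd.DataFrame) -> BehavioralSummary:
    """Score one cell: RT over correct trials, ER over all trials, IES.

    Omitted responses should already be coded as incorrect with missing RT.
    A cell with no correct trials yields NaN RT/IES and ``undefined_rt``;
    an error rate of 1 yields ``infinite_ies``.  Such cells are excluded
    from downstream modelling by :func:`zscore_measures`.
    """
    if len(trials) == 0:
        raise ValueError("a cell must contain at least one trial")
    correct = trials["correct"].to_numpy(dtype=bool)
    n = len(trials)
    n_correct = int(correct.sum())
    er = 1.0 - n_correct / n
    if n_correct == 0:
        return BehavioralSummary(math.nan, er, math.nan, n, 0, undefined_rt=True,
                                 infinite_ies=er == 1.0)
    mean_rt = float(trials.loc[correct, "rt_ms"].mean())
    if er >= 1.0:  # unreachable when n_correct > 0; kept for clarity
        ies = math.inf
    else:
        ies = mean_rt / (1.0 - er)
    return BehavioralSummary(mean_rt, er, ies, n, n_correct)


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every cell of a trial table.

    Expects columns ``subject, condition, timepoint, block, rt_ms, correct``
    and returns one row per cell with ``rt`` (ms, correct trials), ``er``,
    ``ies`` (ms) plus bookkeeping columns.
    """
    missing = set(CELL_KEYS + ["rt_ms", "correct"]) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    rows = []
    for keys, grp in trials.groupby(CELL_KEYS, sort=True):
        s = summarize_cell(grp)
        rows.append(
            dict(
                zip(CELL_KEYS, keys),
                rt=s.mean_rt_correct_ms,
                er=s.error_rate,
                ies=s.ies_ms,
                n_trials=s.n_trials,
                n_correct=s.n_correct,
                undefined_rt=s.undefined_rt,
            )
        )
    return pd.DataFrame(rows)


def zscore_measures(
    summaries: pd.DataFrame,
    pool: str = "pre",
    measures: tuple[str, ...] = ("rt", "er", "ies"),
) -> pd.DataFrame:
    """Attach z-scored measures (``z_rt``, ``z_er``, ``z_ies``).

    Parameters
    ----------
    summaries
        Output of :func:`summarize_trials`.
    pool
        Normalisation pool, per measure and per block:

        - ``"pre"`` (default): all subjects' pre-intervention cells; the
          pre-pool mean/sd standardise both timepoints.
        - ``"global"``: all cells.
        - ``"condition"``: all cells within each condition separately.

    Cells with undefined RT are dropped (with their count recorded in the
    ``attrs`` of the result).  Raises if a pool has fewer than two cells or
    zero variance.
    """
    df = summaries.copy()
    n_dropped = int(df["undefined_rt"].sum()) if "undefined_rt" in df else 0
    if n_dropped:
        df = df.loc[~df["undefined_rt"]].copy()
    if pool == "pre":
        group_cols = ["block"]
        ref = df[df["timepoint"] == "pre"]
    elif pool == "global":
        group_cols = ["block"]
        ref = df
    elif pool == "condition":
        group_cols = ["block", "condition"]
        ref = df
    else:
        raise ValueError(f"unknown pool: {pool!r}")

    for measure in measures:
        stats = ref.groupby(group_cols)[measure].agg(["mean", "std", "count"])
        if (stats["count"] < 2).any():
            raise ValueError(f"normalisation pool for {measure!r} has < 2 cells")
        if (stats["std"] == 0).any() or stats["std"].isna().any():
            raise ValueError(f"degenerate (zero-variance) pool for {measure!r}")
        merged = df.merge(
            stats.reset_index(), on=group_cols, how="left", validate="many_to_one"
        )
        df[f"z_{measure}"] = (
            (merged[measure].to_numpy() - merged["mean"].to_numpy())
            / merged["std"].to_numpy()
        )
    df.attrs["pool"] = pool
    df.attrs["n_dropped_cells"] = n_dropped
    return df
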