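"""Trial filtering, participant exclusion, centring and grouping rules.

The cleaning rules follow the study's reporting: correct trials slower than
50 ms are retained; correct presses under 50 ms (including pre-cue presses,
logged as negative RT) are anticipatory and removed; participants whose
share of correct responses is anticipatory in more than ``rate_threshold``
of cases across at least ``min_blocks`` blocks are excluded outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANTICIPATORY_MS = 50.0


@dataclass
class CleanTable:
    """Retained trials plus per-participant summaries and the exclusion log."""

    trials: pd.DataFrame
    summaries: pd.DataFrame
    excluded: list[str]
    log: dict = field(default_factory=dict)


def flag_anticipatory(trials: pd.DataFrame) -> pd.Series:
    """Correct presses faster than 50 ms (negative RT = pre-cue press)."""
    return trials["correct"].astype(bool) & (trials["rt_ms"] < ANTICIPATORY_MS)


def exclude_anticipators(
    trials: pd.DataFrame,
    rate_threshold: float = 0.10,
    min_blocks: int = 2,
    denominator: str = "correct",
) -> list[str]:
    """Participants with anticipatory shares above threshold in >= min_blocks blocks.

    The share is computed per block over correct responses ("multiple
    blocks" is read as at least two); set ``denominator="all"`` to divide by
    all responses instead.
    """
    if denominator not in ("correct", "all"):
        raise ValueError("denominator must be 'correct' or 'all'")
    df = trials.assign(_antic=flag_anticipatory(trials))
    if denominator == "correct":
        df = df[df["correct"].astype(bool)]
    rates = df.groupby(["participant", "block"])["_antic"].mean()
    n_over = (rates > rate_threshold).groupby("participant").sum()
    return sorted(n_over.index[n_over >= min_blocks])


def filter_valid(
    trials: pd.DataFrame,
    rate_threshold: float = 0.10,
    min_blocks: int = 2,
) -> CleanTable:
    """Apply exclusions then retain correct, non-anticipatory trials > 50 ms."""
    excluded = exclude_anticipators(trials, rate_threshold, min_blocks)
    antic = flag_anticipatory(trials)
    keep = (
        trials["correct"].astype(bool)
        & (trials["rt_ms"] > ANTICIPATORY_MS)
        & ~antic
        & ~trials["participant"].isin(excluded)
    )
    retained = trials[keep].copy()
    if retained.empty:
        warnings.warn("no trials retained after filtering")

    per = trials[~trials["participant"].isin(excluded)]
    summaries = (
        per.groupby("participant")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_rt_ms": g.loc[
                        g["correct"].astype(bool) & (g["rt_ms"] > ANTICIPATORY_MS), "rt_ms"
                    ].mean(),
                    "pct_correct": 100.0 * g["correct"].mean(),
                    "pct_anticipatory": 100.0
                    * (g["correct"].astype(bool) & (g["rt_ms"] < ANTICIPATORY_MS)).sum()
                    / max(int(g["correct"].sum()), 1),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    log = {
        "n_input": int(len(trials)),
        "n_retained": int(len(retained)),
        "n_incorrect": int((~trials["correct"].astype(bool)).sum()),
        "n_anticipatory": int(antic.sum()),
        "excluded_participants": excluded,
    }
    return CleanTable(trials=retained, summaries=summaries, excluded=excluded, log=log)


def mean_centre(clean: CleanTable | pd.DataFrame) -> pd.DataFrame:
    """Add ``rt_centred``: RT minus the participant's mean retained RT."""
    df = clean.trials if isinstance(clean, CleanTable) else clean
    out = df.copy()
    out["rt_centred"] = out["rt_ms"] - out.groupby("participant")["rt_ms"].transform("mean")
    return out


def median_split(scores: pd.Series) -> pd.Series:
    """Label scores strictly below the median "low", the rest "high".

    Ties at the median go to the high group (deterministic; keeps group
    sizes within one when scores are distinct).
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 participants")
    med = scores.median()
    if scores.nunique() == 1:
        warnings.warn("all scores identical; everyone assigned to the high group")
    return pd.Series(
        np.where(scores < med, "low", "high"), index=scores.index, name="rhythm_group"
    )
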