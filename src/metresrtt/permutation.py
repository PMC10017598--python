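"""Per-participant accent relative difference and its restricted permutation test.

For each participant, the accent relative difference (ARD)

    ARD = |x̄_accented − x̄_unaccented| / (|x̄_accented + x̄_unaccented| / 2)

is a dimensionless, sign-free measure of how far accented and unaccented
reaction times diverge during learning.  Its null distribution is built by
shuffling each participant's retained learning-block RTs against the accent
labels *within response key and block* — the restriction keeps key- and
block-specific RT structure intact, so only the accent assignment is
exchangeable under the null.  A participant is flagged when the observed
ARD exceeds the 95th percentile of the null; p-values use the add-one
estimator and are corrected across participants with the Benjamini–Hochberg
step-up procedure.

The public surface follows the model/results idiom: build an
:class:`AccentPermutation` from a (cleaned) trial table, call ``fit``, and
read the per-participant table, counts and ``summary()`` off the results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

LEARNING_BLOCKS = tuple(range(1, 9))


def accent_relative_difference(mean_accented: float, mean_unaccented: float) -> float:
    """Absolute difference of the two means divided by their arithmetic mean."""
    if mean_accented <= 0 or mean_unaccented <= 0:
        raise ValueError("means must be positive (use raw, filtered RTs)")
    return abs(mean_accented - mean_unaccented) / (abs(mean_accented + mean_unaccented) / 2.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PermutationResult:
    """Observed statistic, null summary and significance for one participant."""

    participant: str
    n_trials: int
    n_accented: int
    mean_accented_rt: float
    mean_unaccented_rt: float
    observed_ard: float
    signed_diff: float  # unaccented − accented, ms
    null_mean: float
    null_p95: float
    percentile: float
    p_value: float
    n_iter: int
    n_degenerate_strata: int
    exceeds_95: bool


def _null_accented_sums(
    rts_by_stratum: list[np.ndarray],
    k_by_stratum: list[int],
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Accented-group RT sums for every permutation, stratum by stratum.

    Within each stratum the RTs are permuted and the first k taken as the
    accented draw (equivalent to sampling k without replacement).  Strata
    with a single accent class contribute a constant and are counted as
    degenerate.
    """
    sums = np.zeros(n_iter)
    degenerate = 0
    for rts, k in zip(rts_by_stratum, k_by_stratum):
        m = rts.size
        if k == 0:
            continue
        if k == m:
            sums += rts.sum()
            degenerate += 1
            continue
        tiled = np.tile(rts, (n_iter, 1))
        rng.permuted(tiled, axis=1, out=tiled)
        sums += tiled[:, :k].sum(axis=1)
    degenerate += sum(1 for k in k_by_stratum if k == 0)
    return sums, degenerate


def permutation_test(
    trials: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
    blocks: Iterable[int] = LEARNING_BLOCKS,
) -> PermutationResult:
    """Restricted permutation test for a single participant's learning trials.

    ``trials`` must already be filtered (correct, > 50 ms) and contain the
    columns participant, block, response_key, accent, rt_ms.  The null
    re-pairs RTs with accent labels within each (response_key, block)
    stratum; the percentile is the share of null ARDs strictly below the
    observed one, and p = (1 + #{null >= observed}) / (1 + n_iter).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = trials[trials["block"].isin(list(blocks))]
    pid = str(df["participant"].iloc[0]) if len(df) else "?"
    accent = df["accent"].to_numpy().astype(bool)
    rt = df["rt_ms"].to_numpy(dtype=float)
    if accent.sum() == 0 or (~accent).sum() == 0:
        raise ValueError(f"participant {pid} lacks one accent class in learning blocks")

    mean_acc = rt[accent].mean()
    mean_unacc = rt[~accent].mean()
    observed = accent_relative_difference(mean_acc, mean_unacc)

    rts_by_stratum, k_by_stratum = [], []
    for _, g in df.groupby(["response_key", "block"], sort=True):
        rts_by_stratum.append(g["rt_ms"].to_numpy(dtype=float))
        k_by_stratum.append(int(g["accent"].astype(bool).sum()))

    acc_sums, degenerate = _null_accented_sums(rts_by_stratum, k_by_stratum, n_iter, rng)
    n_acc, n_tot = int(accent.sum()), rt.size
    null_mean_acc = acc_sums / n_acc
    null_mean_unacc = (rt.sum() - acc_sums) / (n_tot - n_acc)
    with np.errstate(divide="ignore", invalid="ignore"):
        null_ard = np.abs(null_mean_acc - null_mean_unacc) / (
            np.abs(null_mean_acc + null_mean_unacc) / 2.0
        )

    # ties (within float tolerance) count against rejection: strata that
    # cannot be reshuffled reproduce the observed statistic exactly up to
    # summation order, and must not register as exceedances
    eps = 1e-9
    percentile = 100.0 * np.mean(null_ard < observed - eps)
    p_value = (1.0 + np.sum(null_ard >= observed - eps)) / (1.0 + n_iter)
    return PermutationResult(
        participant=pid,
        n_trials=n_tot,
        n_accented=n_acc,
        mean_accented_rt=float(mean_acc),
        mean_unaccented_rt=float(mean_unacc),
        observed_ard=float(observed),
        signed_diff=float(mean_unacc - mean_acc),
        null_mean=float(null_ard.mean()),
        null_p95=float(np.quantile(null_ard, 0.95)),
        percentile=float(percentile),
        p_value=float(p_value),
        n_iter=n_iter,
        n_degenerate_strata=degenerate,
        exceeds_95=bool(percentile > 95.0),
    )


class AccentPermutation:
    """Cohort-level model object for the accent permutation analysis.

    Parameters
    ----------
    trials : cleaned trial table (every row correct and > 50 ms).
    blocks : blocks treated as learning; defaults to 1–8.
    """

    def __init__(self, trials: pd.DataFrame, blocks: Iterable[int] = LEARNING_BLOCKS):
        self.trials = trials
        self.blocks = tuple(blocks)

    @classmethod
    def from_clean(cls, clean, blocks: Iterable[int] = LEARNING_BLOCKS):
        return cls(clean.trials, blocks=blocks)

    def fit(self, n_iter: int = 10_000, seed: int | None = None) -> "AccentPermutationResults":
        ss = np.random.SeedSequence(seed)
        pids = sorted(self.trials["participant"].unique())
        rows = []
        for child, pid in zip(ss.spawn(len(pids)), pids):
            res = permutation_test(
                self.trials[self.trials["participant"] == pid],
                n_iter=n_iter,
                seed=np.random.default_rng(child),
                blocks=self.blocks,
            )
            rows.append(vars(res))
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["q_value"] = bh_fdr(frame["p_value"])
        else:
            frame["q_value"] = []
        return AccentPermutationResults(frame, n_iter=n_iter, blocks=self.blocks)


class AccentPermutationResults:
    """Per-participant permutation results with FDR-adjusted q-values."""

    def __init__(self, frame: pd.DataFrame, n_iter: int, blocks: tuple[int, ...]):
        self.frame = frame
        self.n_iter = n_iter
        self.blocks = blocks

    @property
    def n_flagged(self) -> int:
        return int(self.frame["exceeds_95"].sum())

    def cohort_summary(self, profiles: pd.DataFrame) -> dict:
        return cohort_accent_summary(self.frame, profiles)

    def summary(self, profiles: pd.DataFrame | None = None) -> str:
        f = self.frame
        lines = [
            "Accent permutation test (restricted shuffle within key x block)",
            f"  participants: {len(f)}   iterations: {self.n_iter}   "
            f"learning blocks: {self.blocks[0]}-{self.blocks[-1]}",
            f"  flagged (> 95th null percentile): {self.n_flagged} / {len(f)}",
        ]
        if len(f):
            faster = int((f["exceeds_95"] & (f["signed_diff"] > 0)).sum())
            slower = int((f["exceeds_95"] & (f["signed_diff"] < 0)).sum())
            lines.append(f"  flagged faster-accented: {faster}   slower-accented: {slower}")
            lines.append(
                f"  median observed ARD: {f['observed_ard'].median():.4f}   "
                f"median q: {f['q_value'].median():.3f}"
            )
        if profiles is not None:
            by = cohort_accent_summary(self.frame, profiles)["by_condition"]
            for cond, d in sorted(by.items()):
                lines.append(
                    f"  metre {cond}/4-style grouping: {d['flagged']} of {d['n']} flagged"
                )
        return "\n".join(lines)


def cohort_accent_summary(results: pd.DataFrame, profiles: pd.DataFrame) -> dict:
    """Flagged counts by metre condition plus signed-difference export."""
    if len(results) == 0:
        return {"n": 0, "flagged": 0, "by_condition": {}, "signed_diff": {}}
    merged = results.merge(
        profiles[["participant", "metre_condition"]], on="participant", how="left", validate="1:1"
    )
    if merged["metre_condition"].isna().any():
        bad = merged.loc[merged["metre_condition"].isna(), "participant"].tolist()
        raise ValueError(f"participants missing from profiles: {bad}")
    by_condition = {
        int(cond): {"n": int(len(g)), "flagged": int(g["exceeds_95"].sum())}
        for cond, g in merged.groupby("metre_condition")
    }
    signed = {
        int(cond): g["signed_diff"].tolist() for cond, g in merged.groupby("metre_condition")
    }
    return {
        "n": int(len(merged)),
        "flagged": int(merged["exceeds_95"].sum()),
        "by_condition": by_condition,
        "signed_diff": signed,
    }
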