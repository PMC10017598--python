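"""Descriptive contrasts for the metre-augmented SRTT.

Test-block versus late-learning comparisons (phase-shifted block 9 vs block
8, new-metre block 11 vs block 10, new-visual block 12 vs pooled blocks 8
and 10), block-boundary windows, standardised disruption scores, their
correlations, and variability-by-accent profiles.  Group summaries report
the mean with a t-based 95% confidence interval; these are descriptive
companions to (not reimplementations of) mixed-model analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CleanTable, median_split


def _trials(clean) -> pd.DataFrame:
    return clean.trials if isinstance(clean, CleanTable) else clean


def _summary_row(values: np.ndarray, label: str) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = values.mean() if n else np.nan
    sd = values.std(ddof=1) if n > 1 else np.nan
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        lo = hi = np.nan
    return {"group": label, "n": n, "mean": mean, "sd": sd, "ci_low": lo, "ci_high": hi}


@dataclass
class ContrastResult:
    """Per-participant differences plus grouped summaries (mean, sd, 95% CI)."""

    name: str
    per_participant: pd.DataFrame  # participant, value (+ grouping columns)
    summary: pd.DataFrame

    def summary_text(self) -> str:
        lines = [self.name]
        for _, r in self.summary.iterrows():
            lines.append(
                f"  {r['group']:<18} n={int(r['n']):>3}  mean={r['mean']:+8.2f}  "
                f"95% CI [{r['ci_low']:.2f}, {r['ci_high']:.2f}]  sd={r['sd']:.2f}"
            )
        return "\n".join(lines)


def _grouped_summary(per: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    rows = [_summary_row(per["value"].to_numpy(), "overall")]
    for col in group_cols:
        if col in per.columns:
            for level, g in per.groupby(col, sort=True):
                rows.append(_summary_row(g["value"].to_numpy(), f"{col}={level}"))
    return pd.DataFrame(rows)


def _attach_groups(per: pd.DataFrame, profiles: pd.DataFrame | None) -> pd.DataFrame:
    if profiles is None:
        return per
    cols = ["participant", "metre_condition"]
    merged = per.merge(profiles[cols + ["rhythm_score"]], on="participant", how="left")
    scores = profiles.set_index("participant")["rhythm_score"]
    groups = median_split(scores)
    merged["rhythm_group"] = merged["participant"].map(groups)
    return merged


def block_contrast(
    clean,
    block_a: int,
    block_b: int,
    profiles: pd.DataFrame | None = None,
) -> ContrastResult:
    """Per-participant mean RT in ``block_b`` minus mean RT in ``block_a``."""
    df = _trials(clean)
    means = (
        df[df["block"].isin([block_a, block_b])]
        .groupby(["participant", "block"])["rt_ms"]
        .mean()
        .unstack()
    )
    missing = means.index[means.isna().any(axis=1)].tolist()
    if missing:
        warnings.warn(f"dropping participants missing a block: {missing}")
        means = means.dropna()
    per = pd.DataFrame(
        {"participant": means.index, "value": (means[block_b] - means[block_a]).to_numpy()}
    )
    per = _attach_groups(per, profiles)
    return ContrastResult(
        name=f"block {block_b} - block {block_a} (ms)",
        per_participant=per,
        summary=_grouped_summary(per, ["metre_condition", "rhythm_group"]),
    )


def boundary_contrast(
    clean,
    pre_block: int,
    post_block: int,
    n_cycles: int = 2,
    profiles: pd.DataFrame | None = None,
) -> ContrastResult:
    """First cycles of the post block minus final cycles of the pre block.

    Windows are counted in scheduled trials (12 per cycle, via the trial
    index within block) and then intersected with retained trials, so
    exclusions shrink a window rather than shifting it.
    """
    df = _trials(clean)
    width = 12 * n_cycles
    pre = df[(df["block"] == pre_block) & (df["trial"] > 120 - width)]
    post = df[(df["block"] == post_block) & (df["trial"] <= width)]
    pre_means = pre.groupby("participant")["rt_ms"].mean()
    post_means = post.groupby("participant")["rt_ms"].mean()
    common = pre_means.index.intersection(post_means.index)
    per = pd.DataFrame(
        {"participant": common, "value": (post_means[common] - pre_means[common]).to_numpy()}
    )
    per = _attach_groups(per, profiles)
    return ContrastResult(
        name=(
            f"boundary: first {n_cycles} cycles of block {post_block} - "
            f"final {n_cycles} of block {pre_block} (ms)"
        ),
        per_participant=per,
        summary=_grouped_summary(per, ["rhythm_group", "metre_condition"]),
    )


def standardized_disruption(
    clean,
    learn_block: int,
    test_block: int,
    sign: str = "slowing",
) -> pd.Series:
    """(mean test RT − mean learning RT) / participant grand-mean RT.

    With the default ``sign="slowing"`` a positive score means the test
    block was slower.  ``sign="raw"`` keeps the literal learning-minus-test
    subtraction order instead.
    """
    if sign not in ("slowing", "raw"):
        raise ValueError("sign must be 'slowing' or 'raw'")
    df = _trials(clean)
    grand = df.groupby("participant")["rt_ms"].mean()
    if (grand <= 0).any():
        raise ValueError("participant grand-mean RT must be positive")
    means = (
        df[df["block"].isin([learn_block, test_block])]
        .groupby(["participant", "block"])["rt_ms"]
        .mean()
        .unstack()
        .dropna()
    )
    score = (means[test_block] - means[learn_block]) / grand[means.index]
    if sign == "raw":
        score = -score
    score.name = f"disruption_{learn_block}_{test_block}"
    return score


def correlate(x, y, method: str = "pearson") -> dict:
    """Correlation coefficient with a Fisher-z 95% CI and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return {"r": float(r), "ci": (float(lo), float(hi)), "p": float(p), "n": int(x.size)}


def correlate_family(pairs: dict[str, tuple], method: str = "pearson") -> pd.DataFrame:
    """Batch correlations with BH-FDR q-values across the family."""
    from .permutation import bh_fdr

    rows = []
    for name, (x, y) in pairs.items():
        d = correlate(x, y, method=method)
        rows.append({"name": name, **{k: d[k] for k in ("r", "p", "n")},
                     "ci_low": d["ci"][0], "ci_high": d["ci"][1]})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    return out


def variability_profile(clean) -> pd.DataFrame:
    """n, mean, sd, cv and log-sd per participant x block x accent cell.

    Cells with fewer than 2 retained trials get NaN sd/cv/log-sd; zero sd
    gives cv 0 and NaN log-sd.
    """
    df = _trials(clean)
    prof = (
        df.groupby(["participant", "block", "accent"])["rt_ms"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    prof.loc[prof["n"] < 2, "sd"] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        prof["cv"] = prof["sd"] / prof["mean"]
        prof["log_sd"] = np.where(prof["sd"] > 0, np.log(prof["sd"]), np.nan)
    prof.loc[prof["sd"] == 0, "cv"] = 0.0
    return prof


def accent_variability_contrast(
    profile: pd.DataFrame, profiles: pd.DataFrame | None = None
) -> ContrastResult:
    """Paired log-sd difference (accented − unaccented) per participant.

    Averaged over blocks and aggregated within metre condition with a
    paired one-sample t-test; a negative mean means accented responses were
    less variable.  This is a descriptive companion to a mixed model.
    """
    wide = (
        profile.groupby(["participant", "accent"])["log_sd"].mean().unstack()
    )
    wide = wide.dropna()
    per = pd.DataFrame(
        {"participant": wide.index, "value": (wide[1] - wide[0]).to_numpy()}
    )
    per = _attach_groups(per, profiles)
    summary = _grouped_summary(per, ["metre_condition"])
    pvals = {}
    for label, g in [("overall", per)] + (
        [(f"metre_condition={c}", g) for c, g in per.groupby("metre_condition")]
        if "metre_condition" in per.columns
        else []
    ):
        vals = g["value"].to_numpy()
        pvals[label] = (
            float(stats.ttest_1samp(vals, 0.0).pvalue) if vals.size > 1 else np.nan
        )
    summary["p_paired_t"] = summary["group"].map(pvals)
    return ContrastResult(
        name="accented - unaccented log-sd (paired)",
        per_participant=per,
        summary=summary,
    )


def new_visual_check(clean, profiles: pd.DataFrame | None = None) -> ContrastResult:
    """Block 12 (novel sequence) minus pooled blocks 8 and 10, per participant."""
    df = _trials(clean)
    if not (df["block"] == 12).any():
        warnings.warn("block 12 absent; new-visual check is empty")
        empty = pd.DataFrame(columns=["participant", "value"])
        return ContrastResult("new visual - late learning (ms)", empty, _grouped_summary(empty, []))
    novel = df[df["block"] == 12].groupby("participant")["rt_ms"].mean()
    late = df[df["block"].isin([8, 10])].groupby("participant")["rt_ms"].mean()
    common = novel.index.intersection(late.index)
    per = pd.DataFrame(
        {"participant": common, "value": (novel[common] - late[common]).to_numpy()}
    )
    per = _attach_groups(per, profiles)
    return ContrastResult(
        name="new visual - late learning (ms)",
        per_participant=per,
        summary=_grouped_summary(per, ["metre_condition"]),
    )
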