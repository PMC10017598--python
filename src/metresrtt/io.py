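"""Canonical file schemas, run configuration and the end-to-end pipeline.

One trial-table schema is shared by the simulator and all readers (comma
separated, UTF-8, '.' decimal).  Every output file embeds the
configuration hash on a leading comment line, so mixed-version inputs can
be refused; identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts as ct
from .design import design_to_frame, write_design_json
from .permutation import AccentPermutation, bh_fdr
from .preprocess import filter_valid, mean_centre
from .simulate import GenParams, simulate_cohort

TRIAL_COLUMNS = [
    "participant",
    "block",
    "role",
    "trial",
    "cycle",
    "position_in_cycle",
    "cue_location",
    "response_key",
    "accent",
    "rt_ms",
    "correct",
]
_INT_COLUMNS = ["block", "trial", "cycle", "position_in_cycle", "cue_location", "accent"]


@dataclass
class RunConfig:
    """Plain-text run configuration; the hash keys all pipeline outputs."""

    seed: int = 0
    gen: dict = field(default_factory=dict)  # GenParams overrides
    n_iter: int = 10_000
    min_blocks: int = 2
    rate_threshold: float = 0.10
    sign: str = "slowing"

    def gen_params(self) -> GenParams:
        return GenParams().replace(**self.gen)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path, config_hash: str | None) -> None:
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def write_trial_table(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    _write_csv(table[TRIAL_COLUMNS], path, config_hash)


def read_trial_table(path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV (strict schema, typed columns)."""
    with open(path) as fh:
        first = fh.readline()
    file_hash = None
    if first.startswith("# config_hash:"):
        file_hash = first.split(":", 1)[1].strip()
    if expect_hash is not None and file_hash is not None and file_hash != expect_hash:
        raise ValueError(f"config hash mismatch: file {file_hash} != expected {expect_hash}")

    df = pd.read_csv(path, comment="#")
    if list(df.columns) != TRIAL_COLUMNS:
        raise ValueError(
            f"trial table header mismatch: got {list(df.columns)}, expected {TRIAL_COLUMNS}"
        )
    if len(df) == 0:
        return df
    if not pd.api.types.is_numeric_dtype(df["rt_ms"]):
        bad = df.loc[pd.to_numeric(df["rt_ms"], errors="coerce").isna()].index
        raise ValueError(f"non-numeric rt_ms at rows {bad[:5].tolist()}")
    for col in _INT_COLUMNS:
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"column {col} must be integer")
    if df["correct"].dtype != bool:
        if set(df["correct"].unique()) <= {True, False, "True", "False"}:
            df["correct"] = df["correct"].astype(bool)
        else:
            raise ValueError("column correct must be boolean")
    dup = df.duplicated(subset=["participant", "block", "trial"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate (participant, block, trial) key: "
            f"({row['participant']}, {row['block']}, {row['trial']})"
        )
    return df


def write_profiles(profiles: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write_csv(profiles, path, config_hash)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Simulate, preprocess, permutation-test and contrast one cohort.

    Writes designs, trials, profiles, the clean table, permutation results
    and a JSON report into ``out_dir`` and returns the report dict.
    """
    params = config.gen_params()
    if params.n_participants < 2:
        raise ValueError("config requires n_participants >= 2")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()

    profiles, designs, trials = simulate_cohort(params, seed=config.seed)
    write_profiles(profiles, out / "profiles.csv", h)
    write_trial_table(trials, out / "trials.csv", h)
    design_labels = {pid: d.label for pid, d in designs.items()}
    write_design_json(next(iter(designs.values())), out / "design_example.json")

    clean = filter_valid(trials, config.rate_threshold, config.min_blocks)
    centred = mean_centre(clean)
    write_trial_table(centred.drop(columns=["rt_centred"]), out / "clean_trials.csv", h)

    perm = AccentPermutation.from_clean(clean).fit(n_iter=config.n_iter, seed=config.seed)
    _write_csv(perm.frame, out / "permutation.csv", h)

    kept = profiles[~profiles["participant"].isin(clean.excluded)]
    phase = ct.block_contrast(clean, 8, 9, profiles=kept)
    newm = ct.block_contrast(clean, 10, 11, profiles=kept)
    bound = ct.boundary_contrast(clean, 8, 9, n_cycles=2, profiles=kept)
    newvis = ct.new_visual_check(clean, profiles=kept)
    varprof = ct.variability_profile(clean)
    varcon = ct.accent_variability_contrast(varprof, profiles=kept)
    _write_csv(varprof, out / "variability_profile.csv", h)

    disr_phase = ct.standardized_disruption(clean, 8, 9, sign=config.sign)
    disr_new = ct.standardized_disruption(clean, 10, 11, sign=config.sign)
    ards = perm.frame.set_index("participant")["observed_ard"]
    fam = {}
    for name, disr in (("ard_vs_phase_shift", disr_phase), ("ard_vs_new_metre", disr_new)):
        common = ards.index.intersection(disr.index)
        if len(common) >= 4:
            fam[name] = (ards[common].to_numpy(), disr[common].to_numpy())
    correlations = ct.correlate_family(fam) if fam else pd.DataFrame()

    def _summ(c: ct.ContrastResult):
        return json.loads(c.summary.to_json(orient="records"))

    report = {
        "config_hash": h,
        "seed": config.seed,
        "n_participants": int(params.n_participants),
        "excluded_participants": clean.excluded,
        "filter_log": clean.log,
        "permutation": {
            "n_iter": config.n_iter,
            "flagged": perm.n_flagged,
            "by_condition": perm.cohort_summary(kept)["by_condition"],
        },
        "contrasts": {
            "phase_shift_block": _summ(phase),
            "new_metre_block": _summ(newm),
            "phase_shift_boundary": _summ(bound),
            "new_visual_check": _summ(newvis),
            "accent_variability": _summ(varcon),
        },
        "correlations": json.loads(correlations.to_json(orient="records"))
        if len(correlations)
        else [],
        "design_labels": design_labels,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def calibrate(
    effect_grid=(0.0, 10.0, 25.0, 50.0),
    n_participants: int = 100,
    n_iter: int = 1000,
    replications: int = 1,
    noise_sd_ms: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I error and power of the permutation test per injected effect.

    Each effect size is injected as a single-component (all-participants)
    accented-slower shift with no decay; the rejection rate is the share of
    participants flagged at the 95th-percentile criterion, with a
    Clopper–Pearson 95% binomial CI.
    """
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(effect_grid) * replications)
    i = 0
    for effect in effect_grid:
        flagged = total = 0
        for _ in range(replications):
            child = ss[i]; i += 1
            params = GenParams(
                n_participants=n_participants,
                accent_weights_metre4=(1.0, 0.0, 0.0) if effect == 0 else (0.0, 0.0, 1.0),
                accent_weights_metre3=(1.0, 0.0, 0.0) if effect == 0 else (0.0, 0.0, 1.0),
                accent_effect_slow_ms=float(effect),
                accent_effect_sd_ms=0.0,
                accent_decay_rate=0.0,
                accent_var_ratio=1.0,  # injected effects are pure mean shifts
                noise_sd_ms=noise_sd_ms,
                anticipator_fraction=0.0,
            )
            run_seed = int(child.generate_state(1)[0] % 2**31)
            profiles, designs, trials = simulate_cohort(params, seed=run_seed)
            clean = filter_valid(trials)
            res = AccentPermutation.from_clean(clean).fit(n_iter=n_iter, seed=run_seed)
            flagged += res.n_flagged
            total += len(res.frame)
        from scipy.stats import beta as _beta

        lo = _beta.ppf(0.025, flagged, total - flagged + 1) if flagged > 0 else 0.0
        hi = _beta.ppf(0.975, flagged + 1, total - flagged) if flagged < total else 1.0
        rows.append(
            {
                "effect_ms": float(effect),
                "n": total,
                "flagged": flagged,
                "rejection_rate": flagged / total,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
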