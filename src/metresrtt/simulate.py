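"""Synthetic participants and trial-level data for the metre-augmented SRTT.

The generator encodes the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any data download:

* per-participant learning curves — reaction time (RT) declines linearly
  across blocks around a lognormal baseline;
* a signed accent effect drawn from a three-component mixture (no effect /
  accented-faster / accented-slower) whose weights differ by metre
  condition, decaying exponentially across blocks;
* disruption effects in the phase-shifted and new-metre test blocks,
  scaled by a rhythm-sensitivity multiplier;
* a Rhythm Score covariate (percent correct out of 40 same/different
  trials) rank-correlated with baseline speed and musical experience via a
  Gaussian copula;
* ~93% correct responses overall and ~2.2% anticipatory (< 50 ms) correct
  presses, with a small fraction of heavy "anticipators".

All randomness flows from a single seed through named substreams
(`numpy.random.SeedSequence.spawn`), so every artefact is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import TaskDesign, build_counterbalance, design_to_frame

RT_FLOOR_MS = 120.0

#: Self-reported musical experience category probabilities (Likert 1..5).
EXPERIENCE_PROBS = (0.105, 0.395, 0.184, 0.211, 0.105)


def _spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of the latent normals giving Spearman rho."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


@dataclass
class GenParams:
    """Population parameters of the generative model (units in comments)."""

    n_participants: int = 46
    p_metre4: float = 26 / 46  # allocation probability of the 4-grouping

    # baseline RT: lognormal, ms
    baseline_log_mean: float = float(np.log(460.0))
    baseline_log_sd: float = 0.21

    # linear learning trend, ms per block (positive = speeding)
    slope_mean_ms: float = 8.28
    slope_sd_ms: float = 3.0

    # signed accent effect (ms added to accented trials): mixture over
    # (zero, accented-faster, accented-slower) components, per metre
    accent_weights_metre4: tuple[float, float, float] = (0.30, 0.35, 0.35)
    accent_weights_metre3: tuple[float, float, float] = (0.85, 0.075, 0.075)
    accent_effect_fast_ms: float = -25.0
    accent_effect_slow_ms: float = 25.0
    accent_effect_sd_ms: float = 8.0
    accent_decay_rate: float = 0.15  # per block, exp(-rate*(block-1))

    # test-block disruptions, ms; multiplied by (1 + sens_scale * z_rhythm)
    phase_shift_ms: float = 20.0
    sensitivity_scale: float = 0.9
    new_metre_ms: float = 15.0  # heterogeneous-sign scale, 3/4 -> 4/4 direction
    new_metre_44_ms: float = -8.0  # mild speeding for the 4/4 -> 3/4 direction
    # latent novel-sequence cost, block 12; the observed contrast against
    # pooled blocks 8/10 is this minus ~3 blocks of continued learning
    # (~25 ms at the default slope), i.e. ~38 ms
    new_visual_ms: float = 63.0

    # trial noise, ms; per-participant sd is lognormal around noise_sd_ms
    noise_sd_ms: float = 60.0
    noise_sd_log_sd: float = 0.2
    lognormal_noise: bool = False  # optional multiplicative trial noise
    accent_var_ratio: float = 0.85  # accented-trial sd multiplier, 4/4 only

    # response accuracy and anticipations
    error_rate_mean: float = 0.07
    error_rate_sd: float = 0.03
    anticipatory_rate_mean: float = 0.0224
    anticipatory_rate_sd: float = 0.0184
    anticipator_fraction: float = 5 / 46
    anticipator_rate: float = 0.18

    # rhythm discrimination accuracy (Beta on [0,1]) and rank-corr targets
    rhythm_acc_mean: float = 0.82
    rhythm_acc_sd: float = 0.12
    rho_rhythm_baseline: float = -0.44
    rho_rhythm_experience: float = 0.65
    rho_baseline_experience: float = -0.45
    #: latent-correlation inflation compensating for the binomial noise the
    #: 40-trial score adds on top of the latent accuracy (score reliability)
    rhythm_attenuation: float = 0.87
    experience_probs: tuple[float, ...] = EXPERIENCE_PROBS

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("p_metre4", "error_rate_mean", "anticipatory_rate_mean",
                     "anticipator_fraction", "anticipator_rate", "rhythm_acc_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for w in (self.accent_weights_metre4, self.accent_weights_metre3):
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w}")
        if self.noise_sd_ms <= 0:
            raise ValueError("noise_sd_ms must be > 0")
        if not 0.0 < self.accent_var_ratio <= 1.0:
            raise ValueError("accent_var_ratio must be in (0,1]")

    def replace(self, **overrides) -> "GenParams":
        d = asdict(self)
        d.update(overrides)
        for k in ("accent_weights_metre4", "accent_weights_metre3", "experience_probs"):
            d[k] = tuple(d[k])
        return GenParams(**d)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _beta_ab(mean: float, sd: float) -> tuple[float, float]:
    var = sd**2
    kappa = mean * (1 - mean) / var - 1.0
    return mean * kappa, (1 - mean) * kappa


def _beta_draws(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Beta draws with the given moments; degenerate cases return constants."""
    if sd == 0.0 or mean in (0.0, 1.0):
        return np.full(n, mean)
    a, b = _beta_ab(mean, sd)
    return rng.beta(a, b, size=n)


def sample_participants(params: GenParams, seed: int) -> pd.DataFrame:
    """Draw a participant population; one row per participant.

    Observed columns: metre_condition, design label, rhythm_score (0-100 on
    a 2.5-point grid), musical_experience (1..5).  Latent columns carry the
    generative parameters used by :func:`simulate_srtt`.
    """
    params.validate()
    children = _seedseq(seed).spawn(2)
    rng, score_ss = np.random.default_rng(children[0]), children[1]
    n = params.n_participants

    # Gaussian copula for (baseline, rhythm accuracy, musical experience)
    att = params.rhythm_attenuation
    r_br = _spearman_to_pearson(np.clip(params.rho_rhythm_baseline / att, -0.99, 0.99))
    r_re = _spearman_to_pearson(np.clip(params.rho_rhythm_experience / att, -0.99, 0.99))
    r_be = _spearman_to_pearson(params.rho_baseline_experience)
    corr = np.array([[1.0, r_br, r_be], [r_br, 1.0, r_re], [r_be, r_re, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), corr, size=n, method="cholesky")
    u = stats.norm.cdf(z)

    baseline = np.exp(params.baseline_log_mean + params.baseline_log_sd * z[:, 0])
    if params.rhythm_acc_sd == 0.0:
        rhythm_acc = np.full(n, params.rhythm_acc_mean)
    else:
        a, b = _beta_ab(params.rhythm_acc_mean, params.rhythm_acc_sd)
        rhythm_acc = stats.beta.ppf(u[:, 1], a, b)
    cuts = np.cumsum(params.experience_probs)[:-1]
    experience = 1 + np.searchsorted(cuts, u[:, 2])

    metre = np.where(rng.random(n) < params.p_metre4, 4, 3)
    slope = rng.normal(params.slope_mean_ms, params.slope_sd_ms, size=n)

    comp_means = np.array([0.0, params.accent_effect_fast_ms, params.accent_effect_slow_ms])
    accent_effect = np.empty(n)
    for cond, weights in ((4, params.accent_weights_metre4), (3, params.accent_weights_metre3)):
        idx = np.flatnonzero(metre == cond)
        comps = rng.choice(3, size=idx.size, p=np.asarray(weights))
        eff = comp_means[comps]
        nonzero = comps != 0
        eff[nonzero] += rng.normal(0.0, params.accent_effect_sd_ms, size=nonzero.sum())
        accent_effect[idx] = eff

    noise_sd = params.noise_sd_ms * np.exp(
        rng.normal(0.0, params.noise_sd_log_sd, size=n) - params.noise_sd_log_sd**2 / 2
    )
    error_rate = _beta_draws(rng, params.error_rate_mean, params.error_rate_sd, n)
    antic_rate = _beta_draws(rng, params.anticipatory_rate_mean, params.anticipatory_rate_sd, n)
    is_anticipator = rng.random(n) < params.anticipator_fraction
    antic_rate = np.where(is_anticipator, params.anticipator_rate, antic_rate)

    sensitivity = 1.0 + params.sensitivity_scale * z[:, 1]

    profiles = pd.DataFrame(
        {
            "participant": [f"P{i + 1:03d}" for i in range(n)],
            "metre_condition": metre,
            "musical_experience": experience,
            "baseline_ms": baseline,
            "slope_ms_per_block": slope,
            "accent_effect_ms": accent_effect,
            "noise_sd_ms": noise_sd,
            "accent_var_ratio": np.where(metre == 4, params.accent_var_ratio, 1.0),
            "error_rate": error_rate,
            "anticipatory_rate": antic_rate,
            "is_anticipator": is_anticipator,
            "disruption_sensitivity": sensitivity,
            "rhythm_z": z[:, 1],
            "rhythm_accuracy": rhythm_acc,
        }
    )
    profiles["rhythm_score"] = simulate_rhythm_scores(profiles, seed=score_ss)
    return profiles


def simulate_rhythm_scores(profiles: pd.DataFrame, seed) -> pd.Series:
    """Percent correct out of 40 discrimination trials (2.5-point grid)."""
    rng = np.random.default_rng(seed)
    correct = rng.binomial(40, np.clip(profiles["rhythm_accuracy"].to_numpy(), 0, 1))
    return pd.Series(100.0 * correct / 40.0, index=profiles.index, name="rhythm_score")


def assign_designs(
    profiles: pd.DataFrame, seed: int
) -> dict[str, TaskDesign]:
    """Cycle each metre condition's participants through its 12 variants."""
    ss = np.random.SeedSequence(seed).spawn(2)
    variants = {
        4: build_counterbalance(int(ss[0].generate_state(1)[0] % 2**31), metre_condition=4),
        3: build_counterbalance(int(ss[1].generate_state(1)[0] % 2**31), metre_condition=3),
    }
    designs: dict[str, TaskDesign] = {}
    counters = {3: 0, 4: 0}
    for _, row in profiles.iterrows():
        cond = int(row["metre_condition"])
        designs[row["participant"]] = variants[cond][counters[cond] % 12]
        counters[cond] += 1
    return designs


def _disruption_ms(role: str, cond: int, sens: float, z_rhythm: float, p: GenParams) -> float:
    if role == "phase_shifted":
        return p.phase_shift_ms * sens
    if role == "new_metre":
        # 3/4 participants hear the new 4/4: slowing for rhythm-sensitive,
        # speeding for insensitive; 4/4 participants mildly speed up.
        return p.new_metre_ms * z_rhythm if cond == 3 else p.new_metre_44_ms
    if role == "new_visual":
        return p.new_visual_ms
    return 0.0


def simulate_srtt(
    profiles: pd.DataFrame,
    designs: Mapping[str, TaskDesign],
    params: GenParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate the full trial table for a cohort.

    RT model per trial::

        rt = baseline - slope*(block-1) + accent * effect * exp(-rate*(block-1))
             + disruption(role) + noise

    Noise is zero-mean Gaussian with the participant's sd, shrunk by
    ``accent_var_ratio`` on accented trials for 4/4 participants.  RT is
    floored at 120 ms except for injected anticipatory responses, which are
    drawn in [-400, 50) ms and marked correct (negative values stand for
    pre-cue presses).  Incorrect responses follow the same RT model.
    """
    params.validate()
    missing = [p for p in profiles["participant"] if p not in designs]
    if missing:
        raise ValueError(f"no design for participants: {missing[:5]}")

    ss = _seedseq(seed)
    tables = []
    for child, (_, prof) in zip(ss.spawn(len(profiles)), profiles.iterrows()):
        rng = np.random.default_rng(child)
        pid = prof["participant"]
        frame = design_to_frame(designs[pid], participant=pid).copy()
        block = frame["block"].to_numpy()
        accent = frame["accent"].to_numpy()
        n = len(frame)

        decay = np.exp(-params.accent_decay_rate * (block - 1))
        disruption = np.array(
            [
                _disruption_ms(
                    role,
                    int(prof["metre_condition"]),
                    float(prof["disruption_sensitivity"]),
                    float(prof["rhythm_z"]),
                    params,
                )
                for role in frame["role"]
            ]
        )
        sd = prof["noise_sd_ms"] * np.where(
            accent.astype(bool), prof["accent_var_ratio"], 1.0
        )
        mean_rt = (
            prof["baseline_ms"]
            - prof["slope_ms_per_block"] * (block - 1)
            + accent * prof["accent_effect_ms"] * decay
            + disruption
        )
        if params.lognormal_noise:
            rt = mean_rt * np.exp(rng.normal(0.0, sd / np.maximum(mean_rt, 1.0), size=n))
        else:
            rt = mean_rt + rng.normal(0.0, 1.0, size=n) * sd
        rt = np.maximum(rt, RT_FLOOR_MS)

        correct = rng.random(n) >= prof["error_rate"]
        anticipatory = correct & (rng.random(n) < prof["anticipatory_rate"])
        rt[anticipatory] = rng.uniform(-400.0, 50.0, size=int(anticipatory.sum()))

        frame["trial"] = frame.groupby("block").cumcount() + 1
        frame["rt_ms"] = rt
        frame["correct"] = correct
        tables.append(frame)

    out = pd.concat(tables, ignore_index=True)
    cols = [
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
    return out[cols]


def simulate_cohort(
    params: GenParams, seed: int
) -> tuple[pd.DataFrame, dict[str, TaskDesign], pd.DataFrame]:
    """Convenience wrapper: population, designs and trials from one seed."""
    ss = _seedseq(seed).spawn(3)
    profiles = sample_participants(params, seed=ss[0])
    designs = assign_designs(profiles, seed=int(ss[1].generate_state(1)[0] % 2**31))
    trials = simulate_srtt(profiles, designs, params, seed=ss[2])
    return profiles, designs, trials
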