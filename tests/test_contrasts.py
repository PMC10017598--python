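"""Test-block contrasts, boundary windows, disruption scores, variability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metresrtt import contrasts as ct
from metresrtt.preprocess import filter_valid
from metresrtt.simulate import GenParams, simulate_cohort
from conftest import toy_trials


def _two_block_table(mean_a=400.0, mean_b=420.0, n=24):
    rows = [("P1", 8, mean_a, True)] * n + [("P1", 9, mean_b, True)] * n
    t = toy_trials(rows)
    t["trial"] = list(range(1, n + 1)) * 2
    return t


class TestBlockContrast:
    def test_toy_difference(self):
        res = ct.block_contrast(_two_block_table(), 8, 9)
        assert res.per_participant["value"].iloc[0] == pytest.approx(20.0)

    def test_identical_blocks_give_zero(self):
        res = ct.block_contrast(_two_block_table(400, 400), 8, 9)
        assert res.per_participant["value"].iloc[0] == pytest.approx(0.0)

    def test_antisymmetric(self, clean):
        ab = ct.block_contrast(clean, 8, 9).per_participant.set_index("participant")
        ba = ct.block_contrast(clean, 9, 8).per_participant.set_index("participant")
        assert np.allclose(ab["value"], -ba["value"])

    def test_participant_missing_block_dropped_with_warning(self):
        t = pd.concat(
            [_two_block_table(), toy_trials([("P2", 8, 300, True)] * 4)],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="missing a block"):
            res = ct.block_contrast(t, 8, 9)
        assert list(res.per_participant["participant"]) == ["P1"]

    def test_recovers_injected_phase_shift_slowing(self):
        """Simulated disruption lands inside the group-level 95% CI."""
        p = GenParams(
            n_participants=100,
            phase_shift_ms=15.0,
            sensitivity_scale=0.0,
            slope_mean_ms=0.0,
            slope_sd_ms=0.0,
            accent_weights_metre4=(1.0, 0.0, 0.0),
            accent_weights_metre3=(1.0, 0.0, 0.0),
            anticipator_fraction=0.0,
        )
        _, _, trials = simulate_cohort(p, seed=31)
        res = ct.block_contrast(filter_valid(trials), 8, 9)
        row = res.summary[res.summary["group"] == "overall"].iloc[0]
        assert row["ci_low"] <= 15.0 <= row["ci_high"]


class TestBoundaryContrast:
    def test_full_window_equals_block_contrast(self, clean):
        full = ct.boundary_contrast(clean, 8, 9, n_cycles=10).per_participant
        block = ct.block_contrast(clean, 8, 9).per_participant
        merged = full.merge(block, on="participant", suffixes=("_w", "_b"))
        assert np.allclose(merged["value_w"], merged["value_b"])

    def test_boundary_step_detected_but_attenuated_blockwise(self):
        rng = np.random.default_rng(8)
        rows = []
        for block in (8, 9):
            for i in range(120):
                rt = 400.0 + rng.normal(0, 5)
                if block == 9 and i < 24:  # step confined to the first 2 cycles
                    rt += 40.0
                rows.append(("P1", block, rt, True))
        t = toy_trials(rows)
        t["trial"] = list(range(1, 121)) * 2
        bound = ct.boundary_contrast(t, 8, 9, n_cycles=2).per_participant["value"].iloc[0]
        block = ct.block_contrast(t, 8, 9).per_participant["value"].iloc[0]
        assert bound == pytest.approx(40.0, abs=5.0)
        assert block < bound / 2

    def test_identical_distributions_near_zero(self):
        rows = [("P1", b, 400, True) for b in (8, 9) for _ in range(120)]
        t = toy_trials(rows)
        t["trial"] = list(range(1, 121)) * 2
        res = ct.boundary_contrast(t, 8, 9, n_cycles=2)
        assert res.per_participant["value"].iloc[0] == pytest.approx(0.0)


class TestStandardizedDisruption:
    def test_zero_when_means_equal(self):
        s = ct.standardized_disruption(_two_block_table(400, 400), 8, 9)
        assert s.iloc[0] == pytest.approx(0.0)

    @staticmethod
    def _table_with_grand_mean_400():
        # learn block mean 400, test block mean 440, early block 360
        # => participant grand mean exactly 400
        rows = (
            [("P1", 1, 360, True)] * 24
            + [("P1", 8, 400, True)] * 24
            + [("P1", 9, 440, True)] * 24
        )
        return toy_trials(rows)

    def test_toy_value_under_slowing_convention(self):
        s = ct.standardized_disruption(self._table_with_grand_mean_400(), 8, 9)
        assert s.iloc[0] == pytest.approx(0.1, abs=1e-6)

    def test_raw_sign_flag_flips(self):
        t = self._table_with_grand_mean_400()
        assert ct.standardized_disruption(t, 8, 9, sign="raw").iloc[0] == pytest.approx(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 10.0))
    def test_scale_invariant(self, scale):
        t = _two_block_table(400, 460)
        scaled = t.assign(rt_ms=t["rt_ms"] * scale)
        a = ct.standardized_disruption(t, 8, 9).iloc[0]
        b = ct.standardized_disruption(scaled, 8, 9).iloc[0]
        assert a == pytest.approx(b)


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert ct.correlate(x, x)["r"] == pytest.approx(1.0)
        assert ct.correlate(x, -x)["r"] == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(2)
        r = ct.correlate(rng.normal(size=1000), rng.normal(size=1000))["r"]
        assert abs(r) < 0.09

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ct.correlate(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ct.correlate([1, 2, 3], [1, 2, 3])

    def test_family_adds_fdr_q(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        fam = ct.correlate_family(
            {"a": (x, x + rng.normal(size=50)), "b": (x, rng.normal(size=50))}
        )
        assert set(fam.columns) >= {"name", "r", "p", "q"}
        assert (fam["q"] >= fam["p"] - 1e-12).all()


class TestVariability:
    def test_toy_cell_statistics(self):
        t = toy_trials([("P1", 1, 390, True), ("P1", 1, 410, True)])
        prof = ct.variability_profile(t)
        row = prof.iloc[0]
        assert row["mean"] == pytest.approx(400.0)
        assert row["sd"] == pytest.approx(14.142, abs=1e-3)
        assert row["cv"] == pytest.approx(0.0354, abs=1e-4)

    def test_constant_cell_zero_cv(self):
        t = toy_trials([("P1", 1, 400, True)] * 3)
        prof = ct.variability_profile(t)
        assert prof["sd"].iloc[0] == 0.0 and prof["cv"].iloc[0] == 0.0

    def test_cv_scale_invariant(self):
        t = toy_trials([("P1", 1, 390, True), ("P1", 1, 410, True)])
        doubled = t.assign(rt_ms=t["rt_ms"] * 2)
        a = ct.variability_profile(t)["cv"].iloc[0]
        b = ct.variability_profile(doubled)["cv"].iloc[0]
        assert a == pytest.approx(b)

    def test_small_cells_have_undefined_sd(self):
        t = toy_trials([("P1", 1, 390, True, 1), ("P1", 1, 410, True, 0)])
        prof = ct.variability_profile(t)
        assert prof["sd"].isna().all()

    def test_single_participant_contrast_equals_own_difference(self):
        rows = [("P1", 1, rt, True, 1) for rt in (380, 400, 420)]
        rows += [("P1", 1, rt, True, 0) for rt in (350, 400, 450)]
        prof = ct.variability_profile(toy_trials(rows))
        res = ct.accent_variability_contrast(prof)
        wide = prof.set_index("accent")["log_sd"]
        assert res.per_participant["value"].iloc[0] == pytest.approx(
            wide.loc[1] - wide.loc[0]
        )

    def test_accent_variance_shrink_shows_in_4_4_only(self, cohort, clean):
        _, profiles, _, _ = cohort
        prof = ct.variability_profile(clean)
        res = ct.accent_variability_contrast(prof, profiles=profiles)
        s = res.summary.set_index("group")
        assert s.loc["metre_condition=4", "mean"] < 0.0
        assert abs(s.loc["metre_condition=3", "mean"]) < abs(
            s.loc["metre_condition=4", "mean"]
        )


class TestNewVisualCheck:
    def test_no_effect_near_zero(self):
        rows = [("P1", b, 400, True) for b in (8, 10, 12) for _ in range(20)]
        t = toy_trials(rows)
        t["trial"] = list(range(1, 21)) * 3
        res = ct.new_visual_check(t)
        assert res.per_participant["value"].iloc[0] == pytest.approx(0.0)

    def test_injected_cost_recovered_within_ci(self):
        p = GenParams(
            n_participants=80,
            new_visual_ms=38.0,
            slope_mean_ms=0.0,
            slope_sd_ms=0.0,
            accent_weights_metre4=(1.0, 0.0, 0.0),
            accent_weights_metre3=(1.0, 0.0, 0.0),
            phase_shift_ms=0.0,
            new_metre_ms=0.0,
            new_metre_44_ms=0.0,
            anticipator_fraction=0.0,
        )
        _, _, trials = simulate_cohort(p, seed=37)
        res = ct.new_visual_check(filter_valid(trials))
        row = res.summary[res.summary["group"] == "overall"].iloc[0]
        assert row["ci_low"] <= 38.0 <= row["ci_high"]

    def test_absent_block_warns_and_returns_empty(self):
        t = toy_trials([("P1", 8, 400, True)] * 4)
        with pytest.warns(UserWarning, match="block 12 absent"):
            res = ct.new_visual_check(t)
        assert res.per_participant.empty
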