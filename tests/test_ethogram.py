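"""Tests of ethogram windowing, fraction/frequency statistics and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from loomkit.config import ALL_CATEGORIES
from loomkit.errors import DesignError, WindowError
from loomkit.ethogram import (
    EpochWindows,
    Ethogram,
    classify_freezing_group,
    compare_groups,
    fraction_table,
    fractions,
    frequencies,
    transition_matrix,
    window_ethogram,
)

FR = 10.0  # coarse frame rate keeps constructed ethograms compact


def etho_from_spans(spans, fr=FR):
    """Build an ethogram from (label, duration_s) spans."""
    labels = []
    for label, dur in spans:
        labels.extend([label] * int(round(dur * fr)))
    return Ethogram(np.array(labels, dtype=object), fr)


class TestBouts:
    def test_run_length_encoding(self):
        etho = etho_from_spans([("walking", 1.0), ("running", 2.0), ("walking", 0.5)])
        bouts = etho.bouts()
        assert [(b.label, b.start_s, b.end_s) for b in bouts] == [
            ("walking", 0.0, 1.0),
            ("running", 1.0, 3.0),
            ("walking", 3.0, 3.5),
        ]

    def test_consecutive_bouts_differ(self):
        etho = etho_from_spans([("walking", 1.0), ("walking", 1.0), ("sniffing", 1.0)])
        labels = [b.label for b in etho.bouts()]
        assert labels == ["walking", "sniffing"]

    def test_defensive_overlay(self):
        etho = etho_from_spans([("walking", 4.0)])
        overlaid = etho.with_defensive(flight=(1.0, 2.0), freezing=[(3.0, 4.0)])
        labels = [b.label for b in overlaid.bouts()]
        assert labels == ["walking", "flight", "walking", "freezing"]


class TestWindowing:
    def trial_windows(self):
        # stimulus at 60 s, refuge 63-90 s
        return EpochWindows.from_events(60.0, 63.0, 90.0)

    def test_bout_clipped_to_pre_window(self):
        etho = etho_from_spans([("sniffing", 55.0), ("walking", 10.0), ("running", 35.0)])
        sub = window_ethogram(etho, self.trial_windows())
        pre = sub["pre"]
        assert pre.window == (0.0, 60.0)
        walking = [b for b in pre.bouts if b.label == "walking"]
        assert walking[0].start_s == 55.0 and walking[0].end_s == 60.0  # clipped at 0 s point

    def test_durations_sum_to_window_length(self):
        etho = etho_from_spans([("sniffing", 30.0), ("walking", 40.0), ("running", 30.0)])
        for sub in window_ethogram(etho, self.trial_windows()).values():
            total = sum(b.duration for b in sub.bouts)
            assert total == pytest.approx(min(sub.duration, etho.duration - sub.window[0]), abs=1 / FR)

    def test_empty_overlap_excluded(self):
        etho = etho_from_spans([("walking", 100.0)])
        sub = window_ethogram(etho, self.trial_windows())
        assert all(b.duration > 0 for b in sub["escape"].bouts)

    def test_missing_refuge_window(self):
        windows = EpochWindows.from_events(60.0, None, None)
        etho = etho_from_spans([("walking", 100.0)])
        sub = window_ethogram(etho, windows)
        assert "refuge" not in sub and "escape" not in sub
        with pytest.raises(WindowError):
            window_ethogram(etho, windows, require=("refuge",))


class TestFractions:
    def test_planted_freezing_share(self):
        etho = etho_from_spans([("walking", 4.0), ("freezing", 3.0), ("sniffing", 3.0)])
        sub = window_ethogram(etho, EpochWindows(pre=(0.0, 10.0), escape=None, refuge=None))["pre"]
        fr = fractions(sub)
        assert fr["freezing"] == pytest.approx(0.30)

    def test_single_category(self):
        etho = etho_from_spans([("grooming", 5.0)])
        sub = window_ethogram(etho, EpochWindows(pre=(0.0, 5.0), escape=None, refuge=None))["pre"]
        assert fractions(sub)["grooming"] == pytest.approx(1.0)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        spans = [(str(rng.choice(ALL_CATEGORIES)), float(rng.uniform(0.2, 2.0))) for _ in range(20)]
        etho = etho_from_spans(spans)
        sub = window_ethogram(
            etho, EpochWindows(pre=(0.0, etho.duration), escape=None, refuge=None)
        )["pre"]
        assert fractions(sub).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_window_rejected(self):
        from loomkit.ethogram import WindowedEthogram

        with pytest.raises(ValueError):
            fractions(WindowedEthogram(window=(1.0, 1.0), bouts=[]))


class TestFrequencies:
    def test_separated_bouts_counted(self):
        etho = etho_from_spans(
            [("freezing", 1.0), ("walking", 1.0), ("freezing", 2.0), ("walking", 1.0)]
        )
        sub = window_ethogram(etho, EpochWindows(pre=(0.0, 5.0), escape=None, refuge=None))["pre"]
        fq = frequencies(sub)
        assert fq.loc["freezing", "count"] == 2
        assert fq.loc["freezing", "per_min"] == pytest.approx(24.0)

    def test_edge_spanning_bout_counts_once(self):
        etho = etho_from_spans([("walking", 2.0), ("freezing", 4.0)])
        sub = window_ethogram(etho, EpochWindows(pre=(0.0, 4.0), escape=None, refuge=None))["pre"]
        assert frequencies(sub).loc["freezing", "count"] == 1

    def test_empty_window_all_zero(self):
        etho = etho_from_spans([("walking", 2.0)])
        sub = window_ethogram(etho, EpochWindows(pre=(10.0, 12.0), escape=None, refuge=None))["pre"]
        assert (frequencies(sub)["count"] == 0).all()

    def test_frequency_positive_where_fraction_positive(self):
        rng = np.random.default_rng(1)
        spans = [(str(rng.choice(ALL_CATEGORIES)), float(rng.uniform(0.2, 1.0))) for _ in range(15)]
        etho = etho_from_spans(spans)
        sub = window_ethogram(
            etho, EpochWindows(pre=(0.0, etho.duration), escape=None, refuge=None)
        )["pre"]
        fr, fq = fractions(sub), frequencies(sub)
        for cat in ALL_CATEGORIES:
            if fr.get(cat, 0) > 0:
                assert fq.loc[cat, "count"] >= 1


class TestTransitions:
    def test_two_state_cycle(self):
        etho = etho_from_spans(
            [("walking", 1.0), ("running", 1.0), ("walking", 1.0), ("running", 1.0)]
        )
        T = transition_matrix(etho)
        assert T.loc["walking", "running"] == pytest.approx(1.0)
        assert T.loc["running", "walking"] == pytest.approx(1.0)

    def test_diagonal_zero_rows_stochastic(self):
        rng = np.random.default_rng(2)
        spans = [(str(rng.choice(ALL_CATEGORIES[:5])), 0.5) for _ in range(40)]
        etho = etho_from_spans(spans)
        T = transition_matrix(etho)
        assert np.allclose(np.diag(T.to_numpy()), 0.0)
        sums = T.sum(axis=1).to_numpy()
        assert np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0))

    def test_needs_two_bouts(self):
        with pytest.raises(ValueError):
            transition_matrix(etho_from_spans([("walking", 3.0)]))


class TestFreezingGroup:
    def test_pre_stimulus_freezing_ignored(self):
        etho = etho_from_spans([("freezing", 2.0), ("walking", 10.0)])
        assert classify_freezing_group(etho, stimulus_onset=5.0) == "Non-Freezing"

    def test_post_stimulus_freezing_detected(self):
        etho = etho_from_spans([("walking", 6.0), ("freezing", 1.0), ("walking", 2.0)])
        assert classify_freezing_group(etho, stimulus_onset=5.0) == "Freezing"


def simulated_fraction_table(rng, n_per_group=20, effect=None):
    """Per-animal Dirichlet fraction tables for two sexes, optional effect.

    ``effect=(category, delta)`` shifts that category's concentration for
    males only.
    """
    cats = list(ALL_CATEGORIES)
    base = np.ones(len(cats)) * 2.0
    rows, design = {}, []
    for sex in ("male", "female"):
        alpha = base.copy()
        if effect is not None and sex == "male":
            alpha[cats.index(effect[0])] += effect[1]
        for i in range(n_per_group):
            aid = f"{sex[0]}{i}"
            rows[aid] = pd.Series(rng.dirichlet(alpha), index=cats)
            design.append({"animal_id": aid, "sex": sex})
    return fraction_table(rows), pd.DataFrame(design)


class TestCompareGroups:
    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(3)
        table, design = simulated_fraction_table(rng)
        cmp = compare_groups(table, design)
        assert (cmp.posthoc["p_adj"] >= cmp.posthoc["p_raw"] - 1e-12).all()
        assert cmp.posthoc["p_raw"].between(0, 1).all()

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            table, design = simulated_fraction_table(rng, effect=("freezing", 25.0))
            cmp = compare_groups(table, design)
            row = cmp.posthoc.set_index("movement").loc["freezing"]
            hits += bool(row["significant"])
        assert hits >= 19

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(5)
        false_alarms = sum(
            compare_groups(*simulated_fraction_table(rng)).any_significant for _ in range(30)
        )
        assert false_alarms <= 6  # familywise alpha 0.05, generous 30-run bound

    def test_degenerate_design_rejected(self):
        rng = np.random.default_rng(6)
        table, design = simulated_fraction_table(rng)
        design["sex"] = "male"
        with pytest.raises(DesignError):
            compare_groups(table, design)

    def test_tukey_mode_multi_level(self):
        rng = np.random.default_rng(7)
        cats = list(ALL_CATEGORIES)[:5]
        rows, design = {}, []
        for age in ("3w", "12w", "8m"):
            for i in range(8):
                aid = f"{age}{i}"
                rows[aid] = pd.Series(rng.dirichlet(np.ones(5) * 2), index=cats)
                design.append({"animal_id": aid, "age": age})
        cmp = compare_groups(
            fraction_table(rows), pd.DataFrame(design), group_col="age", posthoc="tukey"
        )
        assert cmp.method == "tukey"
        assert cmp.posthoc["p_raw"].between(0, 1).all()

    def test_arcsine_transform_runs(self):
        rng = np.random.default_rng(8)
        table, design = simulated_fraction_table(rng)
        cmp = compare_groups(table, design, transform="arcsine")
        assert len(cmp.posthoc) == len(ALL_CATEGORIES)
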