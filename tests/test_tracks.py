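"""Comet-track filtering, tip estimation, growth metrics and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonmt import synth
from axonmt.tracks import (
    axon_tip,
    bootstrap_median_ci,
    filter_tracks,
    growth_metrics,
    orientation_fraction,
    per_axon_growth_summary,
    qc_axon,
    shrinkage_metrics,
)


class TestFilterTracks:
    def test_six_track_fixture(self, six_track_fixture):
        """The engineered fixture yields the hand-derived survivors and
        per-rule removal counts."""
        table, expected_survivors, expected_removals = six_track_fixture
        survivors, log = filter_tracks(table)
        assert set(survivors["track_id"].unique()) == expected_survivors
        assert dict(zip(log["rule"], log["n_removed"])) == expected_removals

    def test_idempotent(self, six_track_fixture):
        table, _, _ = six_track_fixture
        once, _ = filter_tracks(table)
        twice, log2 = filter_tracks(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (log2["n_removed"] == 0).all()

    def test_three_frame_track_removed(self, make_track):
        t = make_track("a", "t0", 1, 10.0, 5.0, 4.0).iloc[:3]
        survivors, log = filter_tracks(t)
        assert survivors.empty
        assert log.set_index("rule").loc[4, "n_removed"] == 1

    def test_fast_track_removed(self, make_track):
        t = make_track("a", "t0", 1, 10.0, 25.0, 10.0)
        survivors, log = filter_tracks(t)
        assert survivors.empty
        assert log.set_index("rule").loc[3, "n_removed"] == 1

    def test_rules_commute(self, six_track_fixture, make_track):
        """Removing rule-2 violators first leaves the rule-4 count unchanged."""
        table, _, _ = six_track_fixture
        _, log_all = filter_tracks(table)
        speeds = (
            table.groupby("track_id")
            .apply(
                lambda g: 60
                * abs(g["x_um"].iloc[-1] - g["x_um"].iloc[0])
                / (g["t_s"].iloc[-1] - g["t_s"].iloc[0]),
                include_groups=False,
            )
        )
        slow = speeds[speeds < 1.5].index
        pre_filtered = table[~table["track_id"].isin(slow)]
        _, log_pre = filter_tracks(pre_filtered)
        assert (
            log_all.set_index("rule").loc[4, "n_removed"]
            == log_pre.set_index("rule").loc[4, "n_removed"]
        )

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_tracks(pd.DataFrame({"x_um": [1.0]}))


class TestAxonTip:
    def test_single_comet(self, make_track):
        t = make_track("a", "t0", 1, 30.0, 5.0, 0.0)
        assert axon_tip(t.iloc[[0]]) == pytest.approx(30.0)

    def test_uniform_positions(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"axon_id": "a", "track_id": np.arange(3000), "direction": 1,
             "t_s": 0.0, "x_um": rng.uniform(0, 100, 3000)}
        )
        assert axon_tip(df) == pytest.approx(95.0, abs=1.0)

    def test_degenerate_positions(self):
        df = pd.DataFrame({"axon_id": "a", "track_id": [0, 1], "direction": 1,
                           "t_s": [0.0, 0.0], "x_um": [12.5, 12.5]})
        assert axon_tip(df) == 12.5

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            axon_tip(pd.DataFrame(columns=["x_um"]))


class TestOrientationFraction:
    @pytest.mark.parametrize("directions,expected", [
        ([1, 1, 1], 1.0),
        ([1, -1, 1, -1], 0.5),
        ([1, 1, 1, -1], 0.75),
    ])
    def test_counts(self, directions, expected):
        df = pd.DataFrame(
            {"axon_id": "a", "track_id": range(len(directions)),
             "direction": directions, "t_s": 0.0, "x_um": 1.0}
        )
        assert orientation_fraction(df) == expected

    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=30),
           st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_invariance_under_reordering_and_translation(self, dirs, shift):
        df = pd.DataFrame(
            {"axon_id": "a", "track_id": range(len(dirs)), "direction": dirs,
             "t_s": 0.0, "x_um": np.linspace(0, 10, len(dirs))}
        )
        base = orientation_fraction(df)
        shuffled = df.sample(frac=1.0, random_state=1)
        shuffled["x_um"] = shuffled["x_um"] + shift
        assert orientation_fraction(shuffled) == base


class TestGrowthMetrics:
    def test_constant_velocity_track(self, make_track):
        t = make_track("a", "t0", 1, 10.0, 5.0, 25.0)
        m = growth_metrics(t, tip=15.0)
        assert len(m) == 1
        assert m["d_g_um"].iloc[0] == pytest.approx(5.0 / 60.0 * 25.0, abs=1e-9)
        assert m["d_g_um"].iloc[0] == pytest.approx(2.083, abs=1e-3)
        assert m["v_g_um_min"].iloc[0] == pytest.approx(5.0)

    def test_bin_straddling(self, make_track):
        tip = 50.0
        near = make_track("a", "near", 1, tip - 5.0, 5.0, 10.0)    # 5 µm from tip
        far = make_track("a", "far", 1, tip - 15.0, 5.0, 10.0)     # 15 µm from tip
        m = growth_metrics(pd.concat([near, far]), tip=tip)
        assert sorted(m["bin"]) == [0, 1]

    def test_start_beyond_tip_clamps_to_bin_zero(self, make_track):
        t = make_track("a", "t0", 1, 52.0, 5.0, 10.0)
        m = growth_metrics(t, tip=50.0)
        assert m["bin"].iloc[0] == 0

    def test_parameter_recovery(self):
        """Generated (v_g, f_g) are recovered within 10% at >= 100 events."""
        params = synth.RegionParams(
            v_g={k: 5.0 for k in synth.MEASURED_DEFAULTS.v_g},
            f_g={k: 0.06 for k in synth.MEASURED_DEFAULTS.f_g},
            events_per_axon=300,
        )
        table, _ = synth.gen_comet_tracks(params, n_axons=1, seed=4)
        m = growth_metrics(table, tip=axon_tip(table))
        pooled_v = (m["v_g_um_min"] * m["n_events"]).sum() / m["n_events"].sum()
        pooled_f = (m["n_events"] / m["f_g_per_s"]).sum() / m["n_events"].sum()
        assert pooled_v == pytest.approx(5.0, rel=0.10)
        assert 1.0 / pooled_f == pytest.approx(0.06, rel=0.10)

    def test_empty_bins_absent(self, make_track):
        t = make_track("a", "t0", 1, 48.0, 5.0, 10.0)
        m = growth_metrics(t, tip=50.0, bin_width=10.0)
        assert set(m["bin"]) == {0}


class TestShrinkage:
    def test_single_event(self):
        df = pd.DataFrame(
            [{"axon_id": "a", "t0_s": 0.0, "x0_um": 20.0, "t1_s": 10.0, "x1_um": 18.0}]
        )
        per_event, per_axon = shrinkage_metrics(df)
        assert per_event["d_s_um"].iloc[0] == pytest.approx(2.0)
        assert per_axon["d_s_um"].iloc[0] == pytest.approx(2.0)

    def test_synthetic_ensemble_centres_on_truth(self):
        events, _ = synth.gen_shrinkage_events(
            v_s=0.1, f_s=0.1 / 2.03, n_axons=60, events_per_axon=40, seed=3
        )
        _, per_axon = shrinkage_metrics(events)
        assert per_axon["d_s_um"].median() == pytest.approx(2.03, rel=0.10)

    def test_zero_length_event_rejected(self):
        df = pd.DataFrame(
            [{"axon_id": "a", "t0_s": 0.0, "x0_um": 20.0, "t1_s": 10.0, "x1_um": 20.0}]
        )
        with pytest.raises(ValueError, match="positive length"):
            shrinkage_metrics(df)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="no shrinkage"):
            shrinkage_metrics(pd.DataFrame(columns=["axon_id", "t0_s", "x0_um",
                                                    "t1_s", "x1_um"]))


class TestBootstrapMedianCI:
    def test_constant_vector(self):
        ci = bootstrap_median_ci([2.5] * 20, seed=0)
        assert ci.median == ci.lower == ci.upper == 2.5

    def test_format_matches_reporting_style(self):
        rng = np.random.default_rng(1)
        ci = bootstrap_median_ci(rng.exponential(2.9, 200), seed=2)
        text = str(ci)
        assert text == f"{ci.median:.2f} [{ci.lower:.2f}, {ci.upper:.2f}]"
        assert ci.lower <= ci.median <= ci.upper

    def test_reproducible(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=50)
        a = bootstrap_median_ci(vals, seed=7)
        b = bootstrap_median_ci(vals, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_coverage_of_true_median(self):
        """95% CI covers the true exponential median in >= 90% of repeats."""
        true_median = np.log(2.0)
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            sample = rng.exponential(1.0, size=1000)
            ci = bootstrap_median_ci(sample, n_resamples=2000, seed=10_000 + i)
            hits += ci.lower <= true_median <= ci.upper
        assert hits >= 0.90 * n_rep

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([1.0])


class TestQC:
    @pytest.mark.parametrize("orientation,v_g,passes", [
        (0.75, 3.0, False),
        (0.9, 2.5, True),
        (0.9, 1.9, False),
        (0.8, 2.0, True),
    ])
    def test_gate(self, orientation, v_g, passes):
        assert qc_axon(orientation, v_g) is passes


def test_per_axon_summary_regions():
    table, truth = synth.gen_comet_tracks(n_axons=6, seed=2)
    summary = per_axon_growth_summary(table)
    assert set(summary["region"]) <= {"near_tip", "shaft"}
    assert (summary["n_events"] > 0).all()
    assert summary.groupby("axon_id")["n_events"].sum().eq(
        synth.MEASURED_DEFAULTS.events_per_axon
    ).all()
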