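"""Arousal-threshold pipeline: background, correction, fits, comparisons."""

import numpy as np
import pandas as pd
import pytest

from zfsleep.startle import (
    background_move_prob,
    build_response_matrix,
    compare_dose_response,
    corrected_response,
    fit_dose_response,
    sleeping_response,
)
from zfsleep.stats import StatsError, fourpl
from zfsleep.synthetic import GroupSpec, SimulationConfig, simulate_plate

from conftest import make_map, make_traces


def toy_matrix(n_larvae=4, n_events=420, bg_rate=0.1, genotype="wt", seed=0):
    rng = np.random.default_rng(seed)
    powers = np.tile(np.round(np.logspace(0, np.log10(36.31), 14), 2), 30)
    rows = []
    for i in range(n_larvae):
        rows.append(pd.DataFrame({
            "larva": f"A{i+1}",
            "genotype": genotype,
            "event": np.arange(n_events),
            "power": powers[:n_events],
            "moved_pre": rng.random(n_events) < bg_rate,
            "moved_post": rng.random(n_events) < 0.5,
        }))
    return pd.concat(rows, ignore_index=True)


class TestBackground:
    def test_42_of_420_prewindows_gives_point_one(self):
        m = toy_matrix(n_larvae=1)
        m["moved_pre"] = False
        m.loc[: 41, "moved_pre"] = True  # 42 of 420
        group, larva = background_move_prob(m)
        assert larva["A1"] == pytest.approx(42 / 420)
        assert group["wt"] == pytest.approx(0.1)

    def test_all_still_group_is_zero(self):
        m = toy_matrix()
        m["moved_pre"] = False
        group, _ = background_move_prob(m)
        assert group["wt"] == 0.0


class TestCorrectedResponse:
    def test_stated_formula(self):
        m = toy_matrix(n_larvae=2)
        m["moved_pre"] = np.arange(len(m)) % 10 == 0  # background 0.1
        m["moved_post"] = np.arange(len(m)) % 5 < 4   # response 0.8
        corr = corrected_response(m)
        assert np.allclose(corr["background"], 0.1)
        assert np.allclose(corr["corrected"], 0.7)

    def test_response_equal_to_background_corrects_to_zero(self):
        m = toy_matrix()
        # background 0.1 overall, and response exactly 0.1 at every power:
        # mark 3 of each power's 30 post-windows (per larva)
        m["moved_pre"] = np.arange(len(m)) % 10 == 0
        post = np.zeros(len(m), dtype=bool)
        for (_, _), grp in m.groupby(["larva", "power"]):
            post[grp.index[:3]] = True
        m["moved_post"] = post
        corr = corrected_response(m)
        assert np.allclose(corr["corrected"], 0.0, atol=1e-12)

    def test_bounds_and_zero_background_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = toy_matrix(bg_rate=0.0, seed=rng.integers(2**31))
            m["moved_post"] = rng.random(len(m)) < rng.uniform(0, 1)
            corr = corrected_response(m)
            assert corr["corrected"].between(-1, 1).all()
            assert np.allclose(corr["corrected"], corr["response"])

    def test_shuffled_tap_order_leaves_estimates_unchanged(self):
        m = toy_matrix(n_larvae=3, seed=9)
        shuffled = m.sample(frac=1, random_state=7).reset_index(drop=True)
        c1 = corrected_response(m).set_index(["genotype", "power"])
        c2 = corrected_response(shuffled).set_index(["genotype", "power"])
        pd.testing.assert_frame_equal(c1.sort_index(), c2.sort_index())


class TestDoseResponseComparison:
    POWERS = np.round(np.logspace(0, np.log10(36.31), 14), 2)

    def _dataset(self, rng, ec50=8.0, noise=0.04):
        y = fourpl(np.log10(self.POWERS), 0.0, 0.8, np.log10(ec50), 1.8)
        return self.POWERS, y + rng.normal(0, noise, 14)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = self._dataset(rng)
        b = self._dataset(rng)
        r1 = compare_dose_response({"x": a, "y": b})
        r2 = compare_dose_response({"y": b, "x": a})
        assert r1.f == pytest.approx(r2.f)
        assert r1.p == pytest.approx(r2.p)

    def test_shifted_ec50_detected(self):
        rng = np.random.default_rng(6)
        r = compare_dose_response({
            "wt": self._dataset(rng, ec50=8.0, noise=0.02),
            "mut": self._dataset(rng, ec50=16.0, noise=0.02),
        })
        assert r.p < 0.01

    def test_different_power_sets_rejected(self):
        rng = np.random.default_rng(7)
        p, y = self._dataset(rng)
        with pytest.raises(StatsError, match="power sets"):
            compare_dose_response({"a": (p, y), "b": (p * 1.1, y)})

    def test_nonpositive_power_rejected(self):
        with pytest.raises(StatsError, match="positive"):
            fit_dose_response([0.0, 1, 2, 4, 8, 16], np.zeros(6))


class TestResponseMatrixFromTraces:
    def test_matrix_flags_follow_trace_windows(self):
        # 5-s bins; tap at bin 20: pre = bin 19, post = bin 20
        act = np.zeros((2, 40))
        act[0, 19] = 1.0  # larva A1 moved right before the tap
        act[1, 20] = 1.0  # larva A2 moved right after
        start = pd.Timestamp("2017-01-10 00:30:00")
        traces = make_traces(act, start=start, bin_seconds=5.0)
        stim = pd.DataFrame({
            "event_time": [start + pd.Timedelta(seconds=100)],
            "kind": ["tap"], "power": [3.02],
        })
        pmap = make_map(["A1", "A2"])
        m = build_response_matrix(traces, stim, pmap)
        m = m.set_index("larva")
        assert bool(m.loc["A1", "moved_pre"]) and not bool(m.loc["A1", "moved_post"])
        assert not bool(m.loc["A2", "moved_pre"]) and bool(m.loc["A2", "moved_post"])

    def test_excluded_wells_never_enter_matrix(self):
        cfg = SimulationConfig(groups=[GroupSpec("wt", 8)], protocol="tap",
                               n_minutes=2880, n_excluded=2)
        sim = simulate_plate(cfg, 21)
        m = build_response_matrix(sim.sub_traces, sim.stim_log, sim.plate_map)
        excluded = set(sim.plate_map.table.index[sim.plate_map.table["excluded"]])
        assert not (set(m["larva"]) & excluded)
        assert m.groupby("larva").size().eq(420).all()


class TestSleepingResponse:
    def _traces_and_log(self, pre_still, responds):
        # one tap; 5-s bins; a minute of pre-window
        act = np.zeros((1, 30))
        if not pre_still:
            act[0, 10] = 1.0  # movement 30 s before the tap
        if responds:
            act[0, 16] = 1.0  # movement in the post window
        start = pd.Timestamp("2017-01-10 00:30:00")
        traces = make_traces(act, start=start, bin_seconds=5.0)
        stim = pd.DataFrame({
            "event_time": [start + pd.Timedelta(seconds=80)],  # bin 16
            "kind": ["tap"], "power": [3.02],
        })
        return traces, stim, make_map(["A1"])

    def test_still_then_moving_counts_as_responding_sleeper(self):
        per_larva, per_group, _ = sleeping_response(*self._traces_and_log(True, True))
        assert per_larva.loc[0, "n_sleeping_trials"] == 1
        assert per_larva.loc[0, "n_responding"] == 1

    def test_movement_before_tap_excludes_trial_from_denominator(self):
        per_larva, per_group, _ = sleeping_response(*self._traces_and_log(False, True))
        assert per_larva.loc[0, "n_sleeping_trials"] == 0
        assert bool(per_group.loc[0, "flagged_no_sleep"])

    def test_multiple_powers_rejected(self):
        traces, stim, pmap = self._traces_and_log(True, True)
        stim = pd.concat([stim, stim.assign(power=5.0,
                                            event_time=stim["event_time"]
                                            + pd.Timedelta(minutes=6))])
        with pytest.raises(ValueError, match="single tap power"):
            sleeping_response(traces, stim, pmap)

    def test_short_iti_rejected(self):
        traces, stim, pmap = self._traces_and_log(True, True)
        stim = pd.concat([stim, stim.assign(event_time=stim["event_time"]
                                            + pd.Timedelta(minutes=1))])
        with pytest.raises(ValueError, match="intertrial"):
            sleeping_response(traces, stim, pmap)
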