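"""ISI-based inhibition latency detection and behavioral pairing."""

import numpy as np
import pytest

from avoidance_ephys.data_model import UnitRecording
from avoidance_ephys.isi_latency import (InhibitionLatencyModel, isi_baseline,
                                         inhibition_latency,
                                         latency_correlation,
                                         per_cell_latency_summary,
                                         latency_records)
from avoidance_ephys.synthetic import SimConfig, simulate_session, simulate_unit

from conftest import make_session, make_trial
from oracles import brute_inhibition_latency, brute_pearson


def unit_with(spikes, unit_id="u1"):
    return UnitRecording(unit_id, "rPL", 300.0, "avoidance",
                         np.asarray(spikes, dtype=float))


class TestInhibitionLatency:
    def test_constructed_long_isi_detected_at_its_start(self, ccfg):
        # regular ~0.1-s pretone ISIs with slight jitter; in the tone a
        # 0.5-s ISI starting 1.2 s after onset is the first qualifier
        onset = 100.0
        rng = np.random.default_rng(1)
        pre = np.cumsum(rng.uniform(0.095, 0.105, 320)) + (onset - 31.0)
        pre = pre[(pre >= onset - 30.0) & (pre < onset)]
        tone = np.concatenate([np.arange(onset, onset + 1.21, 0.1),
                               [onset + 1.7],
                               np.arange(onset + 1.8, onset + 5.0, 0.1)])
        u = unit_with(np.unique(np.concatenate([pre, tone])))
        trial = make_trial(1, onset)
        lat, reason = inhibition_latency(u, trial, ccfg)
        assert reason == "ok"
        assert lat == pytest.approx(1.2, abs=0.05)

    def test_silent_pretone_unscorable(self, ccfg):
        u = unit_with(np.arange(100.0, 130.0, 0.2))  # spikes only in tone
        lat, reason = inhibition_latency(u, make_trial(1, 100.0), ccfg)
        assert lat is None and reason == "unscorable_baseline"
        base = isi_baseline(u, make_trial(1, 100.0), ccfg)
        assert not base.scorable

    def test_straddling_isi_excluded(self, ccfg):
        # the huge ISI starts pretone (99.9 -> 105), so it must not count;
        # the first in-window qualifier starts at 105
        onset = 100.0
        pre = 70.0 + np.cumsum(np.tile([0.09, 0.11], 149))
        u = unit_with(np.concatenate([pre, [105.0], [112.0],
                                      np.arange(112.1, 115, 0.1)]))
        lat, reason = inhibition_latency(u, make_trial(1, onset), ccfg)
        assert reason == "ok"
        assert lat == pytest.approx(5.0)

    def test_matches_brute_force_on_poisson_trains(self, ccfg, rng):
        hits = 0
        for _ in range(100):
            rate = rng.uniform(3, 10)
            spikes = np.cumsum(rng.exponential(1 / rate, size=2000))
            spikes = spikes[spikes < 200.0]
            u = unit_with(spikes)
            trial = make_trial(1, 60.0, shock=False)
            lat, _ = inhibition_latency(u, trial, ccfg)
            expect = brute_inhibition_latency(spikes, 60.0)
            if lat is None:
                assert expect is None
            else:
                hits += 1
                assert lat == pytest.approx(expect, abs=1e-9)
        assert hits > 20  # the comparison actually exercised detections

    def test_latency_bounds(self, ccfg, rng):
        cfg = SimConfig()
        sess = simulate_session(cfg, "avoidance", rng)
        for _ in range(20):
            u = simulate_unit(cfg, "inhibited_brief", sess, rng)
            for tr in sess.trials:
                lat, _ = inhibition_latency(u, tr, ccfg)
                if lat is not None:
                    assert 0.0 <= lat < 30.0

    def test_detection_fraction_monotone_in_duration(self, ccfg):
        # longer inhibition -> no fewer cells with a qualifying ISI
        fracs = []
        for dur in (1.0, 4.0, 16.0):
            rng = np.random.default_rng(99)
            cfg = SimConfig(inhibit_brief_s=dur, inhibit_onset_lo_s=0.0,
                            inhibit_onset_hi_s=0.0, inhibit_floor_hz=0.5)
            sess = simulate_session(cfg, "avoidance", rng)
            units = [simulate_unit(cfg, "inhibited_brief", sess, rng,
                                   unit_id=f"u{i}", baseline_rate_hz=6.0)
                     for i in range(60)]
            res = InhibitionLatencyModel(units, sess, ccfg).fit()
            fracs.append(res.fraction_with_qualifying_isi())
        assert fracs[0] <= fracs[1] + 0.05
        assert fracs[1] <= fracs[2] + 0.05


class TestSummaries:
    def test_single_trial_cell_means_equal_that_trial(self, ccfg):
        import pandas as pd
        rec = pd.DataFrame([
            {"unit_id": "a", "trial_id": 1, "inhibition_latency_s": 2.0,
             "platform_latency_s": 4.0, "headturn_latency_s": 3.5,
             "avoided": True},
            {"unit_id": "a", "trial_id": 2, "inhibition_latency_s": np.nan,
             "platform_latency_s": 5.0, "headturn_latency_s": np.nan,
             "avoided": True},
        ])
        out = per_cell_latency_summary(rec)
        assert len(out) == 1
        assert out.loc[0, "mean_inhibition_latency_s"] == 2.0
        assert out.loc[0, "mean_platform_latency_s"] == 4.0
        assert out.loc[0, "n_trials"] == 1

    def test_three_trial_cell_arithmetic_means(self):
        import pandas as pd
        rec = pd.DataFrame({
            "unit_id": ["a"] * 3 + ["b"],
            "trial_id": [1, 2, 3, 1],
            "inhibition_latency_s": [1.0, 2.0, 6.0, 9.0],
            "platform_latency_s": [2.0, 4.0, 9.0, 1.0],
            "headturn_latency_s": [np.nan] * 4,
            "avoided": [True, True, True, False],
        })
        out = per_cell_latency_summary(rec).set_index("unit_id")
        assert out.loc["a", "mean_inhibition_latency_s"] == pytest.approx(3.0)
        assert out.loc["a", "mean_platform_latency_s"] == pytest.approx(5.0)
        assert "b" not in out.index  # no avoided trial with a detection

    def test_summary_equals_groupby_oracle(self, ccfg, rng):
        cfg = SimConfig()
        sess = simulate_session(cfg, "avoidance", rng)
        units = [simulate_unit(cfg, "inhibited_brief", sess, rng,
                               unit_id=f"u{i}") for i in range(8)]
        rec = latency_records(units, sess, ccfg)
        out = per_cell_latency_summary(rec).set_index("unit_id")
        ok = rec[rec["avoided"] & rec["inhibition_latency_s"].notna()]
        for uid, grp in ok.groupby("unit_id"):
            assert out.loc[uid, "mean_inhibition_latency_s"] == pytest.approx(
                grp["inhibition_latency_s"].sum() / len(grp))

    def test_missing_headturn_is_nan_not_zero(self, ccfg):
        sess = make_session([make_trial(1, 100.0,
                                        platform_intervals_s=[(104.0, 131.0)])])
        rec = latency_records([unit_with(np.arange(0, 140, 0.2))], sess, ccfg)
        assert np.isnan(rec.loc[0, "headturn_latency_s"])
        assert rec.loc[0, "platform_latency_s"] == pytest.approx(4.0)


class TestCorrelation:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        assert latency_correlation(x, x)[0] == pytest.approx(1.0)
        assert latency_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_hand_table(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [2.0, 1.0, 4.0, 3.0, 7.0]
        r, p = latency_correlation(xs, ys)
        assert r == pytest.approx(brute_pearson(xs, ys), abs=1e-12)
        assert abs(r) <= 1.0

    def test_nan_pairs_dropped(self):
        r, _ = latency_correlation([1, 2, 3, np.nan], [2, 4, 6, 1.0])
        assert r == pytest.approx(1.0)
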