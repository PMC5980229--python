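"""Peri-event binning, z-scoring, classification, and population views."""

import numpy as np
import pytest

from avoidance_ephys.data_model import ClassifierConfig, UnitRecording
from avoidance_ephys.event_aligned import (PeriEventModel, ZRow,
                                           classify_response, heatmap_matrix,
                                           inhibition_duration_class,
                                           is_putative_projection,
                                           overlap_venn, peri_event_counts,
                                           time_resolved_proportions, zscore)
from avoidance_ephys.synthetic import SimConfig, simulate_session, simulate_unit

from conftest import make_session, make_trial
from oracles import brute_bin_counts


def unit_with(spikes, **kw):
    kw.setdefault("unit_id", "u1")
    kw.setdefault("region", "rPL")
    kw.setdefault("spike_width_us", 300.0)
    kw.setdefault("group", "avoidance")
    return UnitRecording(spike_times_s=np.asarray(spikes, dtype=float), **kw)


def zrow_from(z):
    z = np.asarray(z, dtype=float)
    return ZRow(z=z, baseline_mean_hz=6.0, baseline_sd_hz=1.0,
                n_trials=5, unclassifiable=False)


class TestPeriEventCounts:
    def test_spikes_at_bin_edges_follow_half_open_convention(self, ccfg):
        sess = make_session([make_trial(1, 100.0)])
        u = unit_with([100.0, 100.5])
        pec = peri_event_counts(u, sess, "tone_onset", ccfg)
        b0 = ccfg.baseline_bins
        assert pec.counts[0, b0] == 1      # spike at 0.0 -> first tone bin
        assert pec.counts[0, b0 + 1] == 1  # spike at 0.5 -> second tone bin

    def test_counts_match_per_spike_oracle(self, ccfg, rng):
        sess = make_session([make_trial(i + 1, 100.0 + 300.0 * i)
                             for i in range(5)])
        for _ in range(100):
            spikes = np.sort(rng.uniform(0, 1600, size=rng.integers(5, 60)))
            spikes = np.unique(spikes)
            u = unit_with(spikes)
            pec = peri_event_counts(u, sess, "tone_onset", ccfg)
            for i, tr in enumerate(sess.trials):
                expect = brute_bin_counts(spikes, tr.tone_onset_s,
                                          ccfg.bin_edges_s,
                                          cut=tr.shock_interval_s[0])
                assert pec.counts[i].tolist() == expect

    def test_mean_bin_count_for_constant_rate(self, ccfg, rng):
        # 6 Hz homogeneous unit: 3 expected spikes per 0.5-s bin per trial
        cfg = SimConfig(n_trials=5)
        sess = simulate_session(cfg, "avoidance", rng)
        counts = []
        for _ in range(30):
            u = simulate_unit(cfg, "none", sess, rng, baseline_rate_hz=6.0)
            counts.append(peri_event_counts(u, sess, "tone_onset", ccfg).counts)
        m = np.mean(counts)
        assert m == pytest.approx(3.0, abs=3 * np.sqrt(3.0 / np.size(counts)))

    def test_no_qualifying_trials_gives_empty_result(self, ccfg):
        sess = make_session([make_trial(1, 100.0)])  # no platform events
        pec = peri_event_counts(unit_with([1.0]), sess, "platform_entry", ccfg)
        assert pec.n_trials == 0
        zr = zscore(pec, ccfg)
        assert zr.unclassifiable

    def test_early_platform_entries_excluded(self, ccfg):
        sess = make_session([
            make_trial(1, 100.0, platform_intervals_s=[(100.5, 131.0)]),
            make_trial(2, 400.0, platform_intervals_s=[(403.0, 431.0)]),
        ])
        pec = peri_event_counts(unit_with([1.0]), sess, "platform_entry", ccfg)
        assert pec.trial_ids == [2]


class TestZScore:
    def test_alternating_baseline_hand_computation(self, ccfg):
        # pretone rates alternating 4 and 8 Hz -> mu 6, sample SD 2.0520;
        # a 2-Hz tone bin then sits at z = -1.9494
        counts = np.zeros((1, ccfg.n_bins))
        counts[0, :20] = np.tile([2.0, 4.0], 10)  # 0.5-s bins: rate 4/8 Hz
        counts[0, 20] = 1.0                        # 2 Hz
        pec_widths = np.full((1, ccfg.n_bins), 0.5)
        from avoidance_ephys.event_aligned import PeriEventCounts
        pec = PeriEventCounts([1], np.array([0.0]), ccfg.bin_edges_s,
                              counts, pec_widths)
        zr = zscore(pec, ccfg)
        assert zr.baseline_mean_hz == pytest.approx(6.0)
        assert zr.baseline_sd_hz == pytest.approx(2.0519567, abs=1e-6)
        assert zr.z[20] == pytest.approx(-1.9494, abs=1e-4)

    def test_constant_baseline_is_unclassifiable(self, ccfg):
        sess = make_session([make_trial(1, 100.0)])
        u = unit_with(np.arange(90.0, 100.0, 0.5))  # perfectly regular pretone
        zr = zscore(peri_event_counts(u, sess, "tone_onset", ccfg), ccfg)
        assert zr.unclassifiable
        lab = classify_response(zr, ccfg, "u1")
        assert lab.label == "unclassifiable"

    def test_pretone_z_centered(self, ccfg, rng):
        cfg = SimConfig(n_trials=5)
        sess = simulate_session(cfg, "avoidance", rng)
        u = simulate_unit(cfg, "none", sess, rng)
        zr = zscore(peri_event_counts(u, sess, "tone_onset", ccfg), ccfg)
        assert np.mean(zr.z[:20]) == pytest.approx(0.0, abs=1e-12)


class TestClassifyResponse:
    @pytest.mark.parametrize("z01,label,trigger", [
        ((3.0, 0.0), "excited", 0),
        ((-1.0, -2.5), "inhibited", 1),
        ((-2.5, 0.0), "inhibited", 0),
        ((2.0, -1.5), "none", None),
        ((2.58, -1.96), "none", None),   # thresholds are strict
    ])
    def test_threshold_rules(self, ccfg, z01, label, trigger):
        z = np.zeros(ccfg.n_bins)
        z[20], z[21] = z01
        lab = classify_response(zrow_from(z), ccfg, "u1")
        assert lab.label == label
        assert lab.trigger_bin == trigger

    def test_classification_invariant_to_spikes_outside_windows(self, ccfg, rng):
        cfg = SimConfig(n_trials=5)
        sess = simulate_session(cfg, "avoidance", rng)
        u = simulate_unit(cfg, "inhibited_brief", sess, rng)
        lab1 = classify_response(
            zscore(peri_event_counts(u, sess, "tone_onset", ccfg), ccfg),
            ccfg, "u")
        # inject a burst between the analysis windows of trials 1 and 2
        gap = sess.trials[0].tone_window_s[1] + 5.0
        extra = np.sort(np.concatenate(
            [u.spike_times_s, gap + rng.uniform(0, 60, 300)]))
        u2 = unit_with(np.unique(extra))
        lab2 = classify_response(
            zscore(peri_event_counts(u2, sess, "tone_onset", ccfg), ccfg),
            ccfg, "u")
        assert lab1.label == lab2.label


class TestPopulationViews:
    def test_proportions_all_zero_z(self, ccfg):
        z = np.zeros((4, ccfg.n_bins))
        df = time_resolved_proportions(z, ccfg)
        assert (df["frac_excited"] == 0).all()
        assert (df["frac_inhibited"] == 0).all()
        assert (df["n_classifiable"] == 4).all()

    def test_proportions_single_unit_excited_at_bin(self, ccfg):
        z = np.zeros((4, ccfg.n_bins))
        z[2, 33] = 3.0
        df = time_resolved_proportions(z, ccfg)
        assert df.loc[33, "frac_excited"] == 0.25
        assert df["frac_excited"].sum() == 0.25

    def test_proportion_sums_bounded(self, ccfg, rng):
        z = rng.normal(size=(50, ccfg.n_bins)) * 2
        df = time_resolved_proportions(z, ccfg)
        assert ((df["frac_excited"] + df["frac_inhibited"]) <= 1.0).all()

    def test_heatmap_is_permutation_sorted_by_onset_z(self, ccfg, rng):
        z = rng.normal(size=(12, ccfg.n_bins))
        ids = [f"u{i:02d}" for i in range(12)]
        zs, ids_s = heatmap_matrix(z, ids, ccfg)
        assert sorted(ids_s) == ids
        key = zs[:, 20:22].mean(axis=1)
        assert np.all(np.diff(key) <= 1e-12)
        # explicit-sort oracle
        expect = sorted(ids, key=lambda u: (-z[ids.index(u), 20:22].mean(), u))
        assert ids_s == expect

    def test_heatmap_tie_break_by_unit_id(self, ccfg):
        z = np.zeros((3, ccfg.n_bins))
        zs, ids = heatmap_matrix(z, ["b", "a", "c"], ccfg)
        assert ids == ["a", "b", "c"]

    @pytest.mark.parametrize("width,rate,expected", [
        (300.0, 6.0, True), (225.0, 6.0, False), (300.0, 15.0, False),
    ])
    def test_projection_criterion_strict(self, ccfg, width, rate, expected):
        u = unit_with([1.0], spike_width_us=width)
        assert is_putative_projection(u, rate, ccfg) is expected

    def test_venn_partitions(self, rng):
        assert overlap_venn({"a": "excited"}, {"b": "excited"})["excited"] == {
            "tone_only": 1, "platform_only": 1, "both": 0}
        same = {"a": "inhibited", "b": "inhibited"}
        assert overlap_venn(same, same)["inhibited"] == {
            "tone_only": 0, "platform_only": 0, "both": 2}
        # random labels vs set arithmetic
        ids = [f"u{i}" for i in range(40)]
        labs = ["excited", "inhibited", "none"]
        t = {u: labs[rng.integers(3)] for u in ids}
        p = {u: labs[rng.integers(3)] for u in ids}
        v = overlap_venn(t, p)
        for pol in ("excited", "inhibited"):
            ts = {u for u in ids if t[u] == pol}
            ps = {u for u in ids if p[u] == pol}
            assert v[pol]["both"] == len(ts & ps)
            assert v[pol]["tone_only"] == len(ts - ps)
            assert v[pol]["platform_only"] == len(ps - ts)
            # partition reconciles with the union
            assert sum(v[pol].values()) == len(ts | ps)


class TestInhibitionDuration:
    def test_sustained_vs_brief_split(self, ccfg):
        z = np.zeros(ccfg.n_bins)
        z[20] = -3.0
        sel = slice(20 + 20, 20 + 56)        # the 10-28 s window
        z[sel] = -2.5
        assert inhibition_duration_class(zrow_from(z), ccfg) == "sustained"
        z[sel] = 0.0
        assert inhibition_duration_class(zrow_from(z), ccfg) == "brief"


class TestModelFit:
    def test_fit_recovers_injected_classes(self, rng):
        cfg = SimConfig(inhibit_onset_lo_s=0.0, inhibit_onset_hi_s=0.5)
        sess = simulate_session(cfg, "avoidance", rng)
        units = []
        truth = []
        for i in range(30):
            rclass = ("none", "excited", "inhibited_brief")[i % 3]
            truth.append(rclass)
            units.append(simulate_unit(cfg, rclass, sess, rng,
                                       unit_id=f"u{i:03d}"))
        res = PeriEventModel(units, sess, "tone_onset").fit()
        labs = [lab.label for lab in res.labels]
        exc_hit = sum(lab == "excited" for lab, t in zip(labs, truth)
                      if t == "excited")
        inh_hit = sum(lab == "inhibited" for lab, t in zip(labs, truth)
                      if t == "inhibited_brief")
        assert exc_hit >= 8       # of 10 injected
        assert inh_hit >= 6       # of 10 injected
        summ = res.summary()
        assert len(summ) == 30
        assert (summ["n_trials"] == 5).all()

    def test_platform_alignment_uses_same_trials_baseline(self, rng):
        cfg = SimConfig(p_avoid=1.0)
        sess = simulate_session(cfg, "avoidance", rng)
        u = simulate_unit(cfg, "none", sess, rng)
        res = PeriEventModel([u], sess, "platform_entry").fit()
        assert res.n_trials_used[0] >= 1
        # baseline is estimated from pretone (tone-aligned) bins
        assert np.isfinite(res.baseline_mean_hz[0])
        assert np.isfinite(res.z[0, 20])
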