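"""Epoch segmentation, dF/F, spike detection, latency taxonomy and cell
categorisation for the mucosal-poking protocol."""

import numpy as np
import pandas as pd
import pytest

from enskit.calcium_epochs import (
    SpikeParams,
    StimulusProtocol,
    TraceSet,
    analyze_traces,
    classify_cell,
    compare_groups,
    compute_dff,
    detect_spikes,
    epoch_latency,
    segment_epochs,
)
from enskit.synthetic_data import SimTraceConfig, gen_traces

PROTO = StimulusProtocol()


class TestProtocolAndSegmentation:
    def test_default_protocol_windows(self):
        assert PROTO.n_epochs == 24 and PROTO.fps == 50
        assert PROTO.stim_window(0) == (20.0, 45.0)
        assert PROTO.post_window(0) == (45.0, 65.0)
        assert PROTO.baseline_window(0) == (0.0, 20.0)

    def test_second_down_marker_sample_index(self):
        # epoch-relative 10 s at 50 fps is sample 500
        assert int(PROTO.t_second_down_s * PROTO.fps) == 500

    def test_all_windows_within_19_min_trace(self):
        wins = segment_epochs(int(1140 * 50), PROTO)
        assert len(wins) == 24
        assert all(w.complete for w in wins)
        assert wins[-1].post[1] <= 1140.0

    def test_truncated_final_epoch_flagged_incomplete(self):
        wins = segment_epochs(int(1090 * 50), PROTO)
        assert not wins[-1].complete
        assert all(w.complete for w in wins[:-1])

    def test_nonincreasing_epoch_starts_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(n_epochs=2, epoch_starts_s=(10.0, 10.0))


class TestComputeDff:
    def test_constant_trace_gives_zeros(self):
        dff = compute_dff(np.full(2000, 50.0), fps=50.0)
        np.testing.assert_allclose(dff, 0.0, atol=1e-12)

    def test_step_doubling_plateaus_at_one(self):
        trace = np.full(6000, 100.0)
        trace[3000:] = 200.0
        dff = compute_dff(trace, fps=50.0, baseline_window_s=30.0)
        assert dff[3400:4200].max() == pytest.approx(1.0, abs=1e-9)

    def test_planted_transient_amplitude_preserved(self):
        rng = np.random.default_rng(0)
        f0 = 100.0
        trace = f0 + rng.normal(0, 1.0, 20000)
        t = np.arange(5000) / 50.0
        trace[8000:13000] += 20.0 * np.exp(-t / 0.7)
        dff = compute_dff(trace, fps=50.0)
        # amplitude relative to the pre-event dF/F level; averaging the
        # onset samples cancels single-sample noise maxima, and the
        # subtraction removes the percentile-baseline offset
        got = dff[8000:8010].mean() - dff[7800:7950].mean()
        expect = (20.0 * np.exp(-np.arange(10) / 50.0 / 0.7)).mean() / f0
        assert got == pytest.approx(expect, rel=0.05)


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_noise(self):
        """< 0.02 spikes/min at z = 3.5 over 20 noise seeds."""
        minutes = 0.0
        n_spikes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 1.0, 60_000)
            spk = detect_spikes(noise, 50.0, SpikeParams(), noise_sd=1.0)
            n_spikes += len(spk)
            minutes += 60_000 / 50.0 / 60.0
        assert n_spikes / minutes < 0.02

    def test_recall_of_5sigma_transients(self):
        """>= 0.95 of planted 5-sigma transients are detected."""
        rng = np.random.default_rng(1)
        fps, sd = 50.0, 1.0
        trace = rng.normal(0, sd, 100_000)
        events = np.arange(500, 99_000, 2_000)
        t = np.arange(3000) / fps
        kernel = 5.0 * sd * np.exp(-t / 0.7)
        for e in events:
            seg = min(3000, len(trace) - e)
            trace[e: e + seg] += kernel[:seg]
        spk = detect_spikes(trace, fps, SpikeParams(), noise_sd=sd)
        hits = sum(np.any(np.abs(spk - e / fps) < 0.3) for e in events)
        assert hits / len(events) >= 0.95

    def test_refractory_merging_of_close_events(self):
        fps = 50.0
        trace = np.zeros(5000)
        t = np.arange(2000) / fps
        for e in (1000, 1005):  # two events 0.1 s apart
            trace[e: e + 2000] += 5.0 * np.exp(-t / 0.7)
        trace += np.random.default_rng(2).normal(0, 0.3, 5000)
        spk = detect_spikes(trace, fps, SpikeParams(min_separation_s=0.5),
                            noise_sd=1.0)
        assert len(spk) == 1


class TestLatencyTaxonomy:
    @pytest.mark.parametrize(
        "latency,expect",
        [
            (0.3, "immediate"),
            (0.49, "immediate"),
            (0.5, "delayed"),  # boundary: "< 0.5 s" taken literally
            (12.0, "delayed"),
            (24.99, "delayed"),
            (25.0, "poststimulus"),
            (30.0, "poststimulus"),
            (44.9, "poststimulus"),
        ],
    )
    def test_boundaries(self, latency, expect):
        res = epoch_latency(20.0, np.array([20.0 + latency]), PROTO)
        assert res["latency_class"] == expect
        assert res["first_latency_s"] == pytest.approx(latency)

    def test_spike_outside_all_windows_is_none(self):
        res = epoch_latency(20.0, np.array([20.0 + 46.0]), PROTO)
        assert res["latency_class"] == "none"
        assert res["n_spikes"] == 0

    def test_spike_count_restricted_to_response_window(self):
        spikes = np.array([20.3, 32.0, 50.0, 70.0])  # last is outside
        res = epoch_latency(20.0, spikes, PROTO)
        assert res["n_spikes"] == 3


class TestClassifyCell:
    def test_no_spikes_is_nonresponding(self):
        assert classify_cell(np.array([]), PROTO) == "nonresponding"

    def test_stim_only_spikes_are_quiescent_responding(self):
        spikes = np.array([PROTO.epoch_starts_s[3] + 0.3])
        assert classify_cell(spikes, PROTO) == "quiescent_responding"

    def test_genuine_baseline_spike_plus_responses_is_spontaneous(self):
        spikes = np.array([5.0, PROTO.epoch_starts_s[0] + 0.3])  # 5 s: lead-in
        assert classify_cell(spikes, PROTO) == "spontaneous"

    def test_poststimulus_spike_not_mistaken_for_spontaneous(self):
        # post window of epoch 0 overlaps baseline of epoch 1 by design
        spikes = np.array([PROTO.epoch_starts_s[0] + 30.0])
        assert classify_cell(spikes, PROTO) == "quiescent_responding"


class TestFullPipelineRecovery:
    def test_planted_latency_classes_recovered(self):
        """Latencies 0.3/12/30 s at 5-sigma map to their classes for all epochs."""
        cfg = SimTraceConfig(
            n_cells=3,
            category_of_cell={c: "quiescent_responding" for c in ("a", "b", "c")},
            planted_latency_s={"a": 0.3, "b": 12.0, "c": 30.0},
            transient=(5.0, 0.7),
            seed=2,
        )
        ts, _ = gen_traces(cfg)
        epochs, cats = analyze_traces(ts, cfg.protocol)
        assert (cats == "quiescent_responding").all()
        expect = {"a": "immediate", "b": "delayed", "c": "poststimulus"}
        for cell, cls in expect.items():
            got = epochs[epochs.cell == cell].latency_class
            assert (got == cls).mean() == 1.0

    def test_category_partition(self):
        cfg = SimTraceConfig(
            n_cells=3,
            category_of_cell={"a": "nonresponding", "b": "quiescent_responding",
                              "c": "spontaneous"},
            planted_latency_s=0.5,
            seed=3,
        )
        ts, _ = gen_traces(cfg)
        _, cats = analyze_traces(ts, cfg.protocol)
        assert len(cats) == 3
        assert cats["a"] == "nonresponding"
        assert cats["b"] == "quiescent_responding"
        assert cats["c"] == "spontaneous"

    def test_traceset_csv_round_trip(self, tmp_path):
        cfg = SimTraceConfig(n_cells=2, seed=4, duration_s=100.0)
        ts, _ = gen_traces(cfg)
        p = tmp_path / "traces.csv"
        ts.to_csv(p)
        back = TraceSet.from_csv(p)
        np.testing.assert_allclose(back.times_s, ts.times_s)
        np.testing.assert_allclose(back.traces.to_numpy(), ts.traces.to_numpy(),
                                   rtol=1e-6)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(a, a.copy())
        assert res["t_p"] == pytest.approx(1.0)

    def test_shifted_distributions_detected_with_power(self):
        """MWU rejects a one-spike shift (n=30/30) in >=80% of 200 seeds."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.poisson(1.0, 30)
            b = rng.poisson(1.0, 30) + 1  # one extra spike per epoch
            res = compare_groups(a, b)
            hits += res["mwu_p"] < 0.05
        assert hits / 200 >= 0.8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])
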