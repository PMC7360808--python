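"""Engine tests: encoding, learning rules, recall, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasemem import (
    SynapticWeights,
    apply_smo_amplification,
    apply_stdp,
    default_config,
    encode_learn_recall,
    run_phase,
    servable_slots,
)

SLOTS = tuple(range(10, 120, 10))


def random_pattern(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 12))
    return tuple(sorted(rng.choice(SLOTS, size=n, replace=False).tolist()))


class TestEncoding:
    def test_single_input_spike_worked_example(self, cfg, attention):
        """Input at t=20 fires only the -10 ms branch, at t=21; soma at t=22."""
        res = run_phase(cfg, attention, (20,), "encoding")
        fired = {b.smo.j: b.dendritic_spikes for b in res.branches if b.dendritic_spikes}
        assert fired == {-1: (21,)}
        assert res.somatic_spikes == (22,)

    def test_no_dendritic_spike_double_counted_while_suprathreshold(self, cfg, attention):
        """The branch potential stays above phi_dend for several ms after the
        crossing (EPSP plateau + spike potential) yet one spike is recorded."""
        res = run_phase(cfg, attention, (20,), "encoding")
        branch = next(b for b in res.branches if b.smo.j == -1)
        tr = res.branch_traces[branch.branch_id]
        above = np.flatnonzero(tr.net >= cfg.soma.phi_dend)
        assert len(above) >= 3  # plateau, not a single sample
        assert branch.dendritic_spikes == (21,)

    @pytest.mark.parametrize("seed", range(6))
    def test_somatic_train_is_input_shifted_by_two_ms(self, cfg, attention, seed):
        pattern = random_pattern(seed)
        res = run_phase(cfg, attention, pattern, "encoding")
        assert res.somatic_spikes == tuple(t + 2 for t in pattern)

    def test_consecutive_slots_all_fire_through_hyperpolarization(self, cfg, attention):
        """11 somatic spikes 10 ms apart: recovery is fast enough for the full burst."""
        res = run_phase(cfg, attention, SLOTS, "encoding")
        assert res.somatic_spikes == tuple(t + 2 for t in SLOTS)

    def test_smo_has_no_effect_on_the_soma(self, cfg):
        """With no spikes anywhere, the somatic trace is flat at rest even
        though every branch oscillates."""
        res = run_phase(cfg, (), (), "encoding")
        assert np.allclose(res.somatic_trace, cfg.soma.resting)
        assert any(np.ptp(tr.smo) > 10 for tr in res.branch_traces.values())

    def test_trace_shapes_and_spike_bounds(self, cfg, attention):
        res = run_phase(cfg, attention, (20, 50), "encoding")
        assert len(res.somatic_trace) == cfg.duration // cfg.dt
        for tr in res.branch_traces.values():
            assert len(tr.net) == cfg.duration
        for spikes in res.dendritic_spikes.values():
            assert all(0 <= t < cfg.duration for t in spikes)

    def test_input_validation(self, cfg, attention):
        with pytest.raises(ValueError):
            run_phase(cfg, attention, (130,), "encoding")  # beyond the run
        with pytest.raises(ValueError):
            run_phase(cfg, attention, (20.5,), "encoding")  # off-grid
        with pytest.raises(ValueError):
            run_phase(cfg, attention, (20,), "recall")  # input silent in recall


class TestLearningRules:
    def test_stdp_potentiates_exactly_the_spiking_branches(self, cfg, attention):
        pattern = (10, 30, 50, 80, 90, 110)
        res = run_phase(cfg, attention, pattern, "encoding")
        updated = apply_stdp(res, cfg)
        learned = [b for b in updated if b.learned]
        assert len(learned) == 6
        assert all(b.weights.w_AE == b.weights.w_AE_max == 0.55 for b in learned)
        assert all(b.weights.w_IE == 0.15 for b in updated)  # input synapse fixed
        untouched = [b for b in updated if not b.learned]
        assert all(b.weights.w_AE == 0.40 for b in untouched)

    def test_potentiation_ratio_is_about_37_percent(self):
        w = SynapticWeights()
        assert w.w_AE_max / w.w_AE == pytest.approx(1.375)

    def test_empty_input_potentiates_nothing(self, cfg, attention):
        res = run_phase(cfg, attention, (), "encoding")
        assert not any(b.learned for b in apply_stdp(res, cfg))

    def test_smo_amplification_scales_amplitude_only(self, cfg, attention):
        res = run_phase(cfg, attention, (20,), "encoding")
        updated = apply_smo_amplification(res, cfg)
        amplified = [b for b in updated if b.smo_amplified]
        assert len(amplified) == 1
        assert amplified[0].smo.h == pytest.approx(9.0)  # 6.0 * 1.5
        assert amplified[0].weights.w_AE == 0.40  # weights untouched
        assert all(b.smo.h == pytest.approx(6.0) for b in updated if not b.smo_amplified)

    def test_learning_on_recall_result_is_a_protocol_bug(self, cfg):
        _, recall = encode_learn_recall(cfg, (20,))
        with pytest.raises(ValueError):
            apply_stdp(recall, cfg)
        with pytest.raises(ValueError):
            apply_smo_amplification(recall, cfg)


class TestRecall:
    def test_no_learning_means_no_recall_spikes(self, cfg, attention):
        """The attention burst alone cannot fire an unpotentiated neuron."""
        res = run_phase(cfg, attention, (), "recall")
        assert res.somatic_spikes == ()
        assert all(s == () for s in res.dendritic_spikes.values())

    @pytest.mark.parametrize("rule", ["stdp", "smo_amp"])
    def test_single_spike_recall_reproduces_encoding(self, cfg, rule):
        enc, rec = encode_learn_recall(cfg, (20,), learning_rule=rule)
        assert enc.somatic_spikes == (22,)
        assert rec.somatic_spikes == enc.somatic_spikes

    def test_six_spike_pattern_recalled_exactly(self, cfg):
        pattern = (10, 30, 50, 80, 90, 110)
        enc, rec = encode_learn_recall(cfg, pattern)
        assert len(rec.somatic_spikes) == 6
        assert rec.somatic_spikes == tuple(t + 2 for t in pattern)

    def test_empty_input_yields_empty_recall(self, cfg):
        enc, rec = encode_learn_recall(cfg, ())
        assert enc.somatic_spikes == rec.somatic_spikes == ()

    @pytest.mark.parametrize("seed", range(8))
    def test_learning_rules_produce_identical_recall(self, cfg, seed):
        pattern = random_pattern(100 + seed)
        _, rec_stdp = encode_learn_recall(cfg, pattern, learning_rule="stdp")
        _, rec_amp = encode_learn_recall(cfg, pattern, learning_rule="smo_amp")
        assert rec_stdp.somatic_spikes == rec_amp.somatic_spikes

    @pytest.mark.parametrize("seed", range(4))
    def test_removing_an_input_spike_never_adds_spikes(self, cfg, seed):
        pattern = random_pattern(200 + seed)
        _, rec_full = encode_learn_recall(cfg, pattern)
        for drop in pattern:
            reduced = tuple(t for t in pattern if t != drop)
            _, rec = encode_learn_recall(cfg, reduced)
            assert set(rec.somatic_spikes) == set(rec_full.somatic_spikes) - {drop + 2}

    def test_sustained_burst_replays_the_pattern_each_cycle(self):
        """A recall burst longer than one SMO cycle replays the stored train
        once per cycle (period ~120 ms), for as long as the burst lasts."""
        cfg = default_config(duration=240)
        enc, rec = encode_learn_recall(cfg, (20, 50))
        assert enc.somatic_spikes == (22, 52)
        assert rec.somatic_spikes == (22, 52, 142, 172)

    def test_recall_requires_a_full_smo_cycle(self, cfg):
        from dataclasses import replace

        short = replace(cfg, duration=60)
        with pytest.raises(ValueError):
            encode_learn_recall(short, (20,))


class TestEngineOracle:
    def test_branch_traces_match_independent_event_summation(self, cfg, attention):
        """Rebuild every branch trace from the event record with the naive
        untruncated sum and compare against the engine within 0.01 mV."""
        import math

        pattern = (10, 30, 50, 80, 90, 110)
        res = run_phase(cfg, attention, pattern, "encoding")
        for b in res.branches:
            tr = res.branch_traces[b.branch_id]
            smo = b.smo
            for t in range(0, cfg.duration, 3):
                total = cfg.soma.resting + smo.h * math.sin(
                    0.002 * math.pi * smo.fq * (t - smo.offset_ms)
                )
                for onset in attention:
                    dt = t - onset
                    if dt >= 0:
                        total += 39.0 * b.weights.w_AE * dt * 2.0 ** (-dt)
                for onset in pattern:
                    dt = t - onset
                    if dt >= 0:
                        total += 39.0 * b.weights.w_IE * dt * 2.0 ** (-dt)
                for onset in b.dendritic_spikes:
                    dt = t - onset
                    if dt >= 0:
                        total += 40.0 * dt * 2.0 ** (-dt)
                assert tr.net[t] == pytest.approx(total, abs=0.01)

    def test_servable_slots_default_layout(self, cfg):
        assert servable_slots(cfg) == SLOTS
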