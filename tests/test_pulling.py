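"""Worm-like-chain tether models, rip detection, statistics, FRET."""

import numpy as np
import pytest

from tunnelfold.pulling import (
    PullTrace,
    TetherModel,
    contour_length_change,
    detect_transitions,
    ewlc_extension,
    force_stats,
    fret_efficiency,
    invert_force,
    odijk_extension,
    refolding_frequency,
    series_extension,
)
from tunnelfold.synthetic import SyntheticTraceConfig, simulate_trace
from tunnelfold.units import KBT_PN_NM


class TestPolymerModels:
    def test_odijk_asymptote(self):
        assert odijk_extension(5e4, 0.65, 10.6) == pytest.approx(10.6, rel=0.01)

    def test_odijk_root_of_formula(self):
        # F = kBT/(4P) zeroes the bracket: outside the model's validity
        F = KBT_PN_NM / (4 * 0.65)
        assert odijk_extension(F, 0.65, 10.6) == pytest.approx(0.0, abs=1e-9)

    def test_odijk_hand_computed(self):
        expected = 10.6 * (1 - 0.5 * np.sqrt(KBT_PN_NM / (20.0 * 0.65)))
        assert odijk_extension(20.0, 0.65, 10.6) == pytest.approx(expected, rel=1e-12)

    def test_odijk_rejects_nonpositive_force(self):
        with pytest.raises(ValueError):
            odijk_extension(0.0, 0.65, 10.6)

    def test_ewlc_hand_computed(self):
        expected = 3400.0 * (1 - 0.5 * np.sqrt(KBT_PN_NM / (30.0 * 50.0)) + 30.0 / 1200.0)
        assert ewlc_extension(30.0, 50.0, 3400.0, 1200.0) == pytest.approx(expected, rel=1e-12)

    def test_ewlc_reduces_to_odijk_when_inextensible(self):
        F = np.linspace(1.0, 50.0, 200)
        diff = ewlc_extension(F, 50.0, 3400.0, 1e15) - odijk_extension(F, 50.0, 3400.0)
        assert np.max(np.abs(diff)) < 1e-6 * 3400.0

    def test_ewlc_stretch_term_is_linear(self):
        S = 1200.0
        F = S * 0.01
        gain = ewlc_extension(F, 50.0, 3400.0, S) - odijk_extension(F, 50.0, 3400.0)
        assert gain == pytest.approx(0.01 * 3400.0, rel=1e-12)


class TestSeriesTether:
    def test_unfolding_releases_contour(self):
        m = TetherModel()
        for F in (5.0, 15.0, 30.0):
            gain = series_extension(F, m, "unfolded") - series_extension(F, m, "folded")
            assert gain > 0
        # at high force the gain approaches delta_Lc minus the folded size
        gain_hi = series_extension(1e4, m, "unfolded") - series_extension(1e4, m, "folded")
        assert gain_hi == pytest.approx(m.delta_Lc - m.folded_size, rel=0.02)

    def test_no_protein_reduces_to_dna(self):
        m = TetherModel(released_contour=0.0, delta_Lc=0.0, folded_size=0.0)
        F = np.linspace(2, 40, 50)
        assert np.allclose(
            series_extension(F, m, "unfolded"),
            ewlc_extension(F, m.P_dna, m.Lc_dna, m.S_dna),
        )

    def test_strictly_increasing_in_force(self):
        m = TetherModel()
        F = np.linspace(0.5, 60, 300)
        x = series_extension(F, m, "folded")
        assert np.all(np.diff(x) > 0)

    @pytest.mark.parametrize("state", ["folded", "unfolded"])
    @pytest.mark.parametrize("F", [5.0, 12.0, 27.0, 50.0])
    def test_invert_round_trip(self, state, F):
        m = TetherModel()
        x = series_extension(F, m, state)
        assert invert_force(x, m, state) == pytest.approx(F, abs=1e-6)

    def test_invert_rejects_beyond_contour(self):
        m = TetherModel()
        with pytest.raises(ValueError, match="beyond"):
            invert_force(5000.0, m)

    def test_invalid_state_label(self):
        with pytest.raises(ValueError, match="folded"):
            series_extension(10.0, TetherModel(), "molten")


def _synthetic(n_cycles=10, seed=0, **kw):
    cfg = SyntheticTraceConfig(n_cycles=n_cycles, seed=seed, **kw)
    trace, truth = simulate_trace(cfg)
    return cfg, trace, truth


class TestDetection:
    def test_planted_events_recovered(self):
        cfg, trace, truth = _synthetic(n_cycles=15, seed=3)
        model = TetherModel(delta_Lc=cfg.delta_Lc)
        events = detect_transitions(trace, model)
        planted = [t for t in truth if t["kind"] == "unfold"]
        got = {e.cycle: e for e in events if e.direction == "unfold"}
        assert len(got) >= 0.8 * len(planted)
        errs = [
            got[t["cycle"]].force - t["force"] for t in planted if t["cycle"] in got
        ]
        assert abs(np.mean(errs)) < 0.8
        assert max(abs(e) for e in errs) < 2.5

    def test_transition_free_trace_is_quiet(self):
        # a tether that never unfolds (zero-rate kinetics analogue): use
        # traces from cycles whose rupture draw fell beyond the ramp
        from tunnelfold.kinetics import DHSParams

        cfg = SyntheticTraceConfig(
            n_cycles=20,
            seed=11,
            unfold=DHSParams(1e-12, 0.05, 30.0),
            refold=DHSParams(1e-12, 0.05, 30.0, direction="refolding"),
        )
        trace, truth = simulate_trace(cfg)
        assert truth == []
        events = detect_transitions(trace, TetherModel(delta_Lc=cfg.delta_Lc))
        assert len(events) == 0

    def test_first_event_rule(self):
        # inject a second artificial jump after the true one: only the
        # first is reported for the pull phase of that cycle
        cfg, trace, truth = _synthetic(n_cycles=6, seed=5)
        model = TetherModel(delta_Lc=cfg.delta_Lc)
        events = detect_transitions(trace, model)
        per_cycle = {}
        for e in events:
            key = (e.cycle, e.direction)
            assert key not in per_cycle, "more than one event of a kind per cycle"
            per_cycle[key] = e


class TestContourLength:
    def test_recovery_within_five_percent(self):
        cfg, trace, truth = _synthetic(n_cycles=25, seed=7)
        model = TetherModel(delta_Lc=cfg.delta_Lc)
        events = [e for e in detect_transitions(trace, model) if e.direction == "unfold"]
        assert len(events) >= 15
        vals = []
        for e in events:
            try:
                vals.append(contour_length_change(e, trace, model).delta_Lc_nm)
            except ValueError:
                pass  # late ruptures leave too little post-segment; flagged unusable
        assert len(vals) >= 10
        assert abs(np.mean(vals) / cfg.delta_Lc - 1.0) < 0.05

    def test_aa_conversion_identity(self):
        cfg, trace, truth = _synthetic(n_cycles=8, seed=9)
        model = TetherModel(delta_Lc=cfg.delta_Lc)
        for ev in detect_transitions(trace, model):
            try:
                ref = contour_length_change(ev, trace, model)
            except ValueError:
                continue
            assert ref.delta_Lc_aa == pytest.approx(
                ref.delta_Lc_nm / model.contour_per_aa
            )
            break
        else:
            pytest.fail("no refinable event found")

    def test_short_segment_rejected(self):
        cfg, trace, truth = _synthetic(n_cycles=5, seed=13)
        model = TetherModel(delta_Lc=cfg.delta_Lc)
        ev = detect_transitions(trace, model)[0]
        bad = type(ev)(
            cycle=ev.cycle, direction=ev.direction, force=ev.force,
            delta_Lc_nm=ev.delta_Lc_nm, delta_Lc_aa=ev.delta_Lc_aa,
            score=ev.score, index=2,
        )
        with pytest.raises(ValueError, match="samples"):
            contour_length_change(bad, trace, model)


class TestStats:
    def test_mean_sem(self):
        stats, _ = force_stats({"a": np.array([10.0, 12.0, 14.0])})
        assert stats[0].mean == pytest.approx(12.0)
        assert stats[0].sem == pytest.approx(np.std([10, 12, 14], ddof=1) / np.sqrt(3))
        assert stats[0].n == 3

    def test_identical_groups_p_one(self):
        _, table = force_stats({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        # U = 0; of the C(6,3)=20 orderings only one is this extreme per
        # side, so the exact two-sided p-value is 2/20 = 0.1
        _, table = force_stats({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert table["U"].iloc[0] in (0.0, 9.0)
        assert table["p"].iloc[0] == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            force_stats({"a": []})

    def test_small_groups_get_nan_pvalue(self):
        _, table = force_stats({"a": [1.0, 2.0], "b": [3.0, 4.0, 5.0]})
        assert np.isnan(table["p"].iloc[0])


class TestRefoldFrequency:
    def test_seventeen_percent(self):
        from tunnelfold.pulling import TransitionEvent

        events = [
            TransitionEvent(cycle=i, direction="refold", force=10.0,
                            delta_Lc_nm=-11.3, delta_Lc_aa=-31.0, score=5.0, index=50)
            for i in range(17)
        ]
        frac, (lo, hi) = refolding_frequency(100, events)
        assert frac == pytest.approx(0.17)
        assert lo < 0.17 < hi

    def test_zero_events(self):
        frac, (lo, hi) = refolding_frequency(50, [])
        assert frac == 0.0 and lo == 0.0 and hi > 0.0

    def test_all_cycles_refold(self):
        from tunnelfold.pulling import TransitionEvent

        events = [
            TransitionEvent(cycle=i, direction="refold", force=10.0,
                            delta_Lc_nm=-11.3, delta_Lc_aa=-31.0, score=5.0, index=50)
            for i in range(10)
        ]
        frac, (lo, hi) = refolding_frequency(10, events)
        assert frac == 1.0 and hi == 1.0


class TestFret:
    def test_half_at_forster_radius(self):
        assert fret_efficiency(65.0, 65.0) == 0.5

    def test_folded_domain_quenches_donor(self):
        assert fret_efficiency(20.0, 65.0) == pytest.approx(
            1.0 / (1.0 + (20.0 / 65.0) ** 6), rel=1e-12
        )
        assert fret_efficiency(20.0, 65.0) > 0.999

    def test_extended_chain_transfers_little(self):
        assert fret_efficiency(100.0, 65.0) == pytest.approx(
            1.0 / (1.0 + (100.0 / 65.0) ** 6), rel=1e-12
        )
        assert fret_efficiency(100.0, 65.0) < 0.08

    def test_strictly_decreasing(self):
        r = np.linspace(5.0, 200.0, 500)
        e = fret_efficiency(r)
        assert np.all(np.diff(e) < 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 65.0)
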