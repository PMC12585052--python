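"""Event extraction, sliding-window rates, cones and LTT curves."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bbmrange import (
    SimConfig,
    cone_series,
    extract_events,
    ltt_curve,
    period_mean_rate,
    simulate_bd_tree,
    simulate_range_evolution,
    sliding_window_rates,
)
from bbmrange.events_rates import AssignmentError


class TestExtractEvents:
    def test_toy_tree_hand_enumeration(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        trans = [e for e in events if e.kind == "transition"]
        orig = [e for e in events if e.kind == "origination"]
        assert len(trans) == 1
        assert trans[0].time == pytest.approx(2.0)  # midpoint of ages 3 and 1
        assert trans[0].from_range == frozenset("X")
        assert trans[0].to_range == frozenset("Y")
        assert sorted(e.time for e in orig) == [1.0, 2.0, 3.0]
        in_situ = {e.time: e.in_situ for e in orig}
        assert in_situ == {3.0: False, 2.0: True, 1.0: True}

    def test_constant_assignment_has_no_transitions(self, toy_tree):
        assign = {v: frozenset("X") for v in range(toy_tree.n_nodes)}
        events = extract_events(toy_tree, assign)
        assert [e.kind for e in events] == ["origination"] * (toy_tree.n_tips - 1)
        assert all(e.in_situ for e in events)

    def test_expansion_counts_as_transition(self, toy_tree, toy_assignment):
        assign = dict(toy_assignment)
        label_id = {toy_tree.labels[i]: int(i) for i in toy_tree.tip_ids}
        assign[label_id["C"]] = frozenset("XY")  # {X} -> {X,Y} on a tip branch
        events = extract_events(toy_tree, assign)
        exp = [e for e in events if e.kind == "transition" and e.node == label_id["C"]]
        assert len(exp) == 1
        assert exp[0].from_range == frozenset("X") and exp[0].to_range == frozenset("XY")

    def test_child_dating_flag(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment, transition_dating="child")
        trans = [e for e in events if e.kind == "transition"]
        assert trans[0].time == pytest.approx(1.0)

    def test_missing_node_named(self, toy_tree, toy_assignment):
        broken = dict(toy_assignment)
        broken.pop(toy_tree.root)
        with pytest.raises(AssignmentError, match=str(toy_tree.root)):
            extract_events(toy_tree, broken)

    def test_events_sorted_old_to_young(self, toy_tree, toy_assignment):
        times = [e.time for e in extract_events(toy_tree, toy_assignment)]
        assert times == sorted(times, reverse=True)


class TestSlidingWindows:
    def test_toy_window_rate_is_five(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        series = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        idx = np.flatnonzero(np.isclose(series.old_edges, 2.0))
        assert len(idx) == 1
        assert series.values[idx[0]] == pytest.approx(5.0, abs=1e-12)  # 1 / 2 lineages / 0.1
        others = np.delete(series.values, idx[0])
        assert np.all(others == 0.0)

    def test_no_events_all_zero(self, toy_tree):
        assign = {v: frozenset("X") for v in range(toy_tree.n_nodes)}
        events = extract_events(toy_tree, assign)
        series = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        assert np.all(series.values == 0.0)

    def test_doubling_width_halves_rate(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        narrow = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        wide = sliding_window_rates(events, toy_tree, "transition", width=0.2, t_max=3.0)
        assert narrow.values.max() == pytest.approx(2 * wide.values.max())

    def test_root_origination_window_dropped_with_zero_lineages(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        series = sliding_window_rates(events, toy_tree, "origination", width=0.1, t_max=3.0)
        # the root split at age 3.0 has no crossing branches; its window goes
        assert not np.any(np.isclose(series.old_edges, 3.0))
        assert series.counts.sum() == 2  # the two younger originations remain

    def test_conservation_total(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        for kind in ("transition", "origination"):
            series = sliding_window_rates(events, toy_tree, kind, width=0.1, t_max=3.0)
            assert series.total_events() == pytest.approx(series.counts.sum(), abs=1e-12)

    @given(seed=st.integers(0, 2000))
    def test_conservation_on_simulated_histories(self, seed):
        cfg = SimConfig(birth=0.8, death=0.1, n_tips=25, seed=seed, gain=0.1, loss=0.5)
        chron = simulate_bd_tree(cfg)
        _, truth = simulate_range_evolution(chron, cfg)
        events = extract_events(chron, truth.node_ranges)
        for kind in ("transition", "origination"):
            series = sliding_window_rates(
                events, chron, kind, width=0.25, t_max=chron.root_age * 0.98
            )
            in_span = [
                e for e in events
                if e.kind == kind and series.old_edges.max() >= e.time > series.old_edges.min() - series.width
            ]
            assert series.total_events() == pytest.approx(series.counts.sum(), abs=1e-9)
            assert series.counts.sum() == len(in_span)


class TestPeriodMean:
    def test_toy_period_mean(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        series = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        assert period_mean_rate(series, 3.0, 1.0) == pytest.approx(0.25, abs=1e-12)

    def test_constant_series_mean_is_constant(self, toy_tree):
        from bbmrange.events_rates import RateSeries

        series = RateSeries(
            kind="transition",
            width=0.1,
            old_edges=np.arange(3.0, 0.0, -0.1),
            values=np.full(30, 0.7),
            lineages=np.ones(30),
            counts=np.full(30, 0.07),
        )
        assert period_mean_rate(series, 2.5, 0.5) == pytest.approx(0.7)

    def test_empty_period_raises(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        series = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        with pytest.raises(ValueError):
            period_mean_rate(series, 0.05, 0.0)

    def test_pooled_estimator(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        series = sliding_window_rates(events, toy_tree, "transition", width=0.1, t_max=3.0)
        # one event, exposure = sum(lineages)*width over the 20 windows in (1,3]
        sel = (series.old_edges > 1.0) & (series.old_edges <= 3.0)
        expected = 1.0 / (series.lineages[sel].sum() * 0.1)
        assert period_mean_rate(series, 3.0, 1.0, pooled=True) == pytest.approx(expected)


class TestCones:
    def test_single_event_triangle(self, toy_tree, toy_assignment):
        events = [e for e in extract_events(toy_tree, toy_assignment) if e.kind == "transition"]
        frame = cone_series(events, toy_tree, "transition", cone_width=0.2, grid_step=0.01, t_max=3.0)
        peak = frame.loc[np.isclose(frame.age_mya, 2.0), "rate"].iloc[0]
        assert peak == pytest.approx(5.0, abs=1e-9)  # 2 * (1/2) / 0.2
        outside = frame[(frame.age_mya > 2.1 + 1e-9) | (frame.age_mya < 1.9 - 1e-9)]
        assert np.all(outside.rate == 0.0)

    def test_no_events_identically_zero(self, toy_tree):
        frame = cone_series([], toy_tree, "transition", t_max=3.0)
        assert np.all(frame.rate == 0.0)

    def test_two_identical_events_double(self, toy_tree, toy_assignment):
        events = [e for e in extract_events(toy_tree, toy_assignment) if e.kind == "transition"]
        one = cone_series(events, toy_tree, "transition", t_max=3.0)
        two = cone_series(events * 2, toy_tree, "transition", t_max=3.0)
        assert np.allclose(two.rate, 2 * one.rate)

    def test_integral_matches_inverse_lineage_sum(self, toy_tree, toy_assignment):
        events = extract_events(toy_tree, toy_assignment)
        kindevents = [e for e in events if e.kind == "transition"]
        frame = cone_series(kindevents, toy_tree, "transition", grid_step=0.001, t_max=3.0)
        integral = np.trapezoid(frame.rate[::-1], frame.age_mya[::-1])
        expected = sum(1.0 / toy_tree.lineages_at(e.time) for e in kindevents)
        assert integral == pytest.approx(expected, abs=1e-6)


class TestLTT:
    def test_whole_toy_tree_steps(self, toy_tree):
        curve = ltt_curve(toy_tree)
        assert curve.breaks.tolist() == [3.0, 2.0, 1.0, 0.0]
        assert curve.counts.tolist() == [2, 3, 4]
        assert curve.value(2.5) == 2
        assert curve.value(0.0) == 4

    def test_cherry_clade_constant_two(self, toy_tree):
        curve = ltt_curve(toy_tree, mrca_of=["A", "B"])
        assert curve.counts.tolist() == [2]
        assert curve.breaks.tolist() == [1.0, 0.0]

    def test_truncation_restricts_curve(self, toy_tree):
        curve = ltt_curve(toy_tree, min_age=0.5)
        assert curve.breaks.tolist() == [3.0, 2.0, 1.0, 0.5]
        assert curve.counts.tolist() == [2, 3, 4]
        assert curve.value(0.5) == 4

    def test_unknown_taxon(self, toy_tree):
        with pytest.raises(Exception, match="Zz"):
            ltt_curve(toy_tree, mrca_of=["A", "Zz"])

    @given(seed=st.integers(0, 2000))
    def test_final_count_equals_tips(self, seed):
        chron = simulate_bd_tree(SimConfig(birth=1.0, death=0.2, n_tips=15, seed=seed))
        curve = ltt_curve(chron)
        assert curve.counts[-1] == chron.n_tips
        assert curve.counts[0] == 2
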