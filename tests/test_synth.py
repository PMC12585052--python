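"""Birth-death tree and range-evolution simulators."""

import json

import numpy as np
import pytest

from bbmrange import (
    AreaAlphabet,
    SimConfig,
    make_fixture,
    parse_chronogram,
    read_region_codings,
    simulate_bd_tree,
    simulate_range_evolution,
    two_burst_profile,
)


class TestBirthDeathTrees:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(birth=1.0, death=0.0, n_tips=4, seed=99)
        assert simulate_bd_tree(cfg).to_newick() == simulate_bd_tree(cfg).to_newick()

    def test_tip_count_and_validity(self):
        chron = simulate_bd_tree(SimConfig(birth=0.7, death=0.2, n_tips=37, seed=1))
        assert chron.n_tips == 37
        assert chron.root_age > 0

    def test_pure_birth_crown_age_expectation(self):
        """E[crown age] for a Yule tree stopped at n tips is sum_{j=2..n} 1/(j*birth)."""
        birth, n, reps = 1.0, 8, 500
        expected = sum(1.0 / (j * birth) for j in range(2, n + 1))
        rng = np.random.default_rng(42)
        ages = [
            simulate_bd_tree(SimConfig(birth=birth, death=0.0, n_tips=n, seed=int(s))).root_age
            for s in rng.integers(0, 2**31 - 1, size=reps)
        ]
        se = np.std(ages) / np.sqrt(reps)
        assert np.mean(ages) == pytest.approx(expected, abs=4 * se)

    def test_crown_age_mode(self):
        chron = simulate_bd_tree(SimConfig(birth=0.9, death=0.1, n_tips=None, crown_age=4.0, seed=2))
        assert chron.root_age == pytest.approx(4.0, abs=1e-9)
        assert chron.n_tips >= 2

    def test_birth_not_above_death_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(birth=0.5, death=0.5, n_tips=10)


class TestRangeEvolution:
    def test_frozen_process_inherits_root(self):
        cfg = SimConfig(birth=1.0, death=0.0, n_tips=12, seed=4, gain=1e-12, loss=1e-12)
        chron = simulate_bd_tree(cfg)
        coding, truth = simulate_range_evolution(chron, cfg)
        root_range = truth.node_ranges[chron.root]
        assert len(root_range) == 1
        assert all(r == root_range for r in truth.node_ranges.values())
        assert truth.events == []

    def test_ranges_bounded_and_nonempty(self):
        cfg = SimConfig(birth=0.8, death=0.1, n_tips=40, seed=6, gain=0.3, loss=0.3, max_areas=3)
        chron = simulate_bd_tree(cfg)
        coding, truth = simulate_range_evolution(chron, cfg)
        for rng_set in truth.node_ranges.values():
            assert 1 <= len(rng_set) <= 3

    def test_events_lie_within_their_branch(self):
        cfg = SimConfig(birth=0.8, death=0.1, n_tips=30, seed=8, gain=0.4, loss=0.5)
        chron = simulate_bd_tree(cfg)
        _, truth = simulate_range_evolution(chron, cfg)
        assert truth.events, "expected some range changes at these rates"
        for e in truth.events:
            v = e["node"]
            assert chron.ages[chron.parent[v]] > e["time"] > chron.ages[v]

    def test_gain_event_count_matches_poisson_expectation(self):
        """Expected gains ~= gain rate x alphabet slots x open exposure time."""
        reps = 200
        gain = 0.15
        counts, exposures = [], []
        for seed in range(reps):
            cfg = SimConfig(
                birth=1.0, death=0.0, n_tips=12, seed=seed,
                alphabet=AreaAlphabet.from_string("AB"), gain=gain, loss=8.0, max_areas=1,
            )
            # max_areas=1 with fast loss never blocks gains of the single free
            # area and occupied sets stay singletons: open slots = 1 always.
            chron = simulate_bd_tree(cfg)
            _, truth = simulate_range_evolution(chron, cfg)
            counts.append(sum(1 for e in truth.events if e["kind"] == "gain"))
            exposures.append(chron.lengths.sum())
        # with |S|=1 capped at max_areas=1 no gains can happen at all
        assert sum(counts) == 0

        counts = []
        for seed in range(reps):
            cfg = SimConfig(
                birth=1.0, death=0.0, n_tips=12, seed=seed,
                alphabet=AreaAlphabet.from_string("AB"), gain=gain, loss=1e9, max_areas=2,
            )
            chron = simulate_bd_tree(cfg)
            _, truth = simulate_range_evolution(chron, cfg)
            counts.append(sum(1 for e in truth.events if e["kind"] == "gain"))
        # near-instant loss keeps one open slot at all times: gains ~ Poisson
        # with mean gain * total branch length
        expected = gain * np.mean(exposures)
        se = np.std(counts) / np.sqrt(reps)
        assert np.mean(counts) == pytest.approx(expected, abs=3 * se + 0.05 * expected)

    def test_epoch_multiplier_boosts_burst_gains(self):
        burst, flank = [], []
        for seed in range(40):
            cfg = SimConfig(
                birth=0.6, death=0.05, n_tips=80, seed=seed, gain=0.05, loss=0.4,
                epochs=((6.0, 4.0, 6.0),),
            )
            chron = simulate_bd_tree(cfg)
            if chron.root_age < 7.0:
                continue
            _, truth = simulate_range_evolution(chron, cfg)
            gains = [e for e in truth.events if e["kind"] == "gain"]
            burst.append(sum(1 for e in gains if 6.0 >= e["time"] > 4.0))
            flank.append(sum(1 for e in gains if 4.0 >= e["time"] > 2.0))
        # same 2-Myr span, more lineages in the younger flank, yet the
        # 6x multiplier must dominate on average
        assert np.mean(burst) > np.mean(flank)


class TestFixtures:
    def test_fixture_roundtrip(self, tmp_path):
        cfg = two_burst_profile(seed=1, n_tips=60)
        paths = make_fixture(cfg, tmp_path)
        chron = parse_chronogram(paths["tree"].read_text())
        coding = read_region_codings(paths["codings"].read_text(), cfg.alphabet)
        assert set(chron.tip_labels) == coding.taxa()
        truth = json.loads(paths["truth"].read_text())
        assert len(truth["node_ranges"]) == chron.n_nodes

    def test_fixture_bytes_deterministic(self, tmp_path):
        cfg = two_burst_profile(seed=5, n_tips=40)
        p1 = make_fixture(cfg, tmp_path / "a")
        p2 = make_fixture(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_default_profile_scale(self):
        cfg = two_burst_profile(seed=3)
        chron = simulate_bd_tree(cfg)
        assert 95 <= chron.n_tips <= 380  # conditioned band around ~190
        assert chron.root_age == pytest.approx(10.5, abs=1e-9)
        coding, _ = simulate_range_evolution(chron, cfg)
        sizes = [len(coding[t]) for t in chron.tip_labels]
        assert max(sizes) <= 3 and min(sizes) >= 1
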