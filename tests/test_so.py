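import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soanfis.so import (Bounds, CandidateTree, Forest, SOConfig,
                        competition_index, competition_phase, init_forest,
                        normalized_strength, optimize, renew_phase,
                        resistance_phase, seeding_phase)

from .conftest import CountingStrength, neg_sphere


def make_forest(strengths, positions=None, generation=1, seed=0):
    if positions is None:
        positions = [np.array([float(i), 0.0]) for i in range(len(strengths))]
    trees = [CandidateTree(np.asarray(p, float), float(s))
             for p, s in zip(positions, strengths)]
    f = Forest(trees=trees, generation=generation,
               rng=np.random.default_rng(seed))
    f._update_best()
    return f


class TestBounds:
    def test_validation(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, np.inf]), np.array([1.0, np.inf]))

    def test_clip_and_contains(self, unit_bounds5):
        x = unit_bounds5.clip(np.full(5, 7.0))
        assert unit_bounds5.contains(x)


class TestConfig:
    def test_rate_ranges(self):
        with pytest.raises(ValueError):
            SOConfig(population_size=1)
        with pytest.raises(ValueError):
            SOConfig(renew_rate=1.5)
        with pytest.raises(ValueError):
            SOConfig(competition_rate=0.0)
        with pytest.raises(ValueError):
            SOConfig(fe_budget=10, population_size=50)

    def test_resistance_defaults_to_seeding(self):
        assert SOConfig(seeding_rate=0.3).effective_resistance_rate == 0.3
        assert SOConfig(seeding_rate=0.3, resistance_rate=0.1).effective_resistance_rate == 0.1

    def test_from_mapping_rejects_unknown(self):
        with pytest.raises(ValueError):
            SOConfig.from_mapping({"psize": 10})


class TestInitForest:
    def test_containment_and_reproducibility(self, unit_bounds5):
        cfg = SOConfig(population_size=50, fe_budget=3000, rng_seed=42)
        f1 = init_forest(unit_bounds5, cfg, neg_sphere)
        f2 = init_forest(unit_bounds5, cfg, neg_sphere)
        assert len(f1) == 50
        for t1, t2 in zip(f1.trees, f2.trees):
            assert unit_bounds5.contains(t1.position)
            np.testing.assert_array_equal(t1.position, t2.position)

    def test_degenerate_interval(self):
        b = Bounds(np.full(4, 0.3), np.full(4, 0.3))
        f = init_forest(b, SOConfig(population_size=5, fe_budget=100, rng_seed=0),
                        neg_sphere)
        for t in f.trees:
            np.testing.assert_array_equal(t.position, np.full(4, 0.3))

    def test_fe_count_equals_population(self, unit_bounds5):
        fn = CountingStrength(neg_sphere)
        cfg = SOConfig(population_size=50, fe_budget=3000, rng_seed=1)
        f = init_forest(unit_bounds5, cfg, fn)
        assert fn.calls == 50
        assert f.fe_used == 50
        assert f.seed_count == 0 and f.generation == 0

    def test_seed_injection(self, unit_bounds5):
        cfg = SOConfig(population_size=5, fe_budget=100, rng_seed=0)
        x0 = np.full(5, 0.5)
        f = init_forest(unit_bounds5, cfg, neg_sphere, seeds=[x0])
        np.testing.assert_array_equal(f.trees[0].position, x0)


class TestNormalizedStrength:
    def test_derived_example(self):
        # direct arithmetic: (S - min) / sum(S)
        f = make_forest([2.0, 1.0, 1.0])
        np.testing.assert_allclose(normalized_strength(f), [0.25, 0.0, 0.0])

    def test_all_equal(self):
        f = make_forest([3.0] * 4)
        np.testing.assert_allclose(normalized_strength(f), np.zeros(4))

    def test_single_tree(self):
        np.testing.assert_allclose(normalized_strength(make_forest([5.0])), [0.0])

    def test_zero_denominator(self):
        f = make_forest([1.0, -1.0])
        np.testing.assert_allclose(normalized_strength(f), [0.0, 0.0])

    def test_empty_forest(self):
        with pytest.raises(ValueError):
            normalized_strength(Forest(trees=[]))


class TestRenew:
    def test_noop_at_generation_zero(self, unit_bounds5, small_config):
        f = init_forest(unit_bounds5, small_config, neg_sphere)
        f.seed_count = 10
        n_before = len(f)
        renew_phase(f, unit_bounds5, small_config, neg_sphere)
        assert len(f) == n_before

    def test_ceil_count(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=200, renew_rate=0.1, rng_seed=0)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        f.generation, f.seed_count = 1, 10
        renew_phase(f, unit_bounds5, cfg, neg_sphere)
        assert len(f) == 11  # ceil(0.1 * 10) = 1 seedling

    def test_zero_rate(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=200, renew_rate=0.0, rng_seed=0)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        f.generation, f.seed_count = 3, 7
        renew_phase(f, unit_bounds5, cfg, neg_sphere)
        assert len(f) == 10


class TestCompetitionIndex:
    def test_single_neighbor_arithmetic(self):
        # one neighbor, S_k = 1, distance 1, lambda = 1 -> Lambda = 1
        lam = competition_index(np.zeros(2), 0.5, np.array([[1.0, 0.0]]),
                                np.array([1.0]), asymmetry_index=0.5)
        assert lam == pytest.approx(1.0)

    def test_weak_neighbor_discounted(self):
        lam = competition_index(np.zeros(2), 2.0, np.array([[1.0, 0.0]]),
                                np.array([1.0]), asymmetry_index=0.5)
        assert lam == pytest.approx(0.5)  # (1 - gamma) factor

    def test_coincident_neighbor_floored(self):
        lam = competition_index(np.zeros(2), 0.0, np.array([[0.0, 0.0]]),
                                np.array([1.0]), asymmetry_index=0.0)
        assert np.isfinite(lam) and lam > 0


class TestCompetitionPhase:
    def test_equal_strength_replacement_boundary(self):
        # cored tree replaced when its strongest neighbor ties (<= rule)
        b = Bounds(np.zeros(2), np.ones(2))
        cfg = SOConfig(population_size=4, fe_budget=100, competition_rate=0.25,
                       growth_scale=1e-9, rng_seed=0)
        # strengths sum positive; tau of the top tree recruits neighbors
        f = make_forest([5.0, 5.0, 1.0, 1.0],
                        positions=[[0.1, 0.1], [0.9, 0.9], [0.2, 0.2], [0.8, 0.8]])
        fixed = 5.0
        competition_phase(f, b, cfg, lambda x: fixed)
        assert f.trees[0].strength == fixed

    def test_zero_tau_untouched(self):
        b = Bounds(np.zeros(2), np.ones(2))
        cfg = SOConfig(population_size=3, fe_budget=100, competition_rate=0.34,
                       rng_seed=0)
        f = make_forest([0.0, 0.0, 0.0])
        before = [t.position.copy() for t in f.trees]
        competition_phase(f, b, cfg, neg_sphere)
        for t, p in zip(f.trees, before):
            np.testing.assert_array_equal(t.position, p)

    def test_bounds_containment_after_phase(self, unit_bounds5):
        cfg = SOConfig(population_size=12, fe_budget=500, growth_scale=0.5,
                       rng_seed=3)
        f = init_forest(unit_bounds5, cfg, lambda x: float(np.sum(x)))
        competition_phase(f, unit_bounds5, cfg, lambda x: float(np.sum(x)))
        for t in f.trees:
            assert unit_bounds5.contains(t.position)


class TestSeeding:
    def test_zero_rate(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=200, seeding_rate=0.0,
                       rng_seed=0)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        seeding_phase(f, unit_bounds5, cfg, neg_sphere)
        assert len(f) == 10 and f.seed_count == 0

    def test_offspring_count_and_stock(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=200, seeding_rate=0.5,
                       rng_seed=0)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        seeding_phase(f, unit_bounds5, cfg, neg_sphere)
        assert len(f) == 15 and f.seed_count == 5

    def test_offspring_within_bounds(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=400, seeding_rate=1.0,
                       rng_seed=7)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        seeding_phase(f, unit_bounds5, cfg, neg_sphere)
        for t in f.trees:
            assert unit_bounds5.contains(t.position)

    def test_one_dimensional_domain(self):
        b = Bounds(np.zeros(1), np.ones(1))
        cfg = SOConfig(population_size=4, fe_budget=100, rng_seed=0)
        f = init_forest(b, cfg, lambda x: float(x[0]))
        seeding_phase(f, b, cfg, lambda x: float(x[0]))  # m = 1 is the only choice
        assert f.seed_count == 2


class TestResistance:
    def test_printed_identity(self):
        # p_w = 1 - (1 - p_s) collapses to p_s
        assert SOConfig(seeding_rate=0.3).effective_resistance_rate == pytest.approx(0.3)

    def test_capacity_restored(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=400, rng_seed=1)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        seeding_phase(f, unit_bounds5, cfg, neg_sphere)
        resistance_phase(f, cfg)
        assert len(f) == 10

    def test_zero_removal_only_trims(self, unit_bounds5):
        cfg = SOConfig(population_size=10, fe_budget=200, seeding_rate=0.0,
                       resistance_rate=0.0, rng_seed=0)
        f = init_forest(unit_bounds5, cfg, neg_sphere)
        resistance_phase(f, cfg)
        assert len(f) == 10 and f.generation == 1

    def test_never_empties(self):
        cfg = SOConfig(population_size=2, fe_budget=10, resistance_rate=1.0,
                       rng_seed=0)
        f = make_forest([1.0, 2.0], generation=0)
        resistance_phase(f, cfg)
        assert len(f) == 1 and f.trees[0].strength == 2.0


class TestOptimize:
    def test_trace_monotone_and_deterministic(self, sphere2_bounds):
        cfg = SOConfig(population_size=20, fe_budget=400, rng_seed=11)
        best1, tr1 = optimize(neg_sphere, sphere2_bounds, cfg)
        best2, tr2 = optimize(neg_sphere, sphere2_bounds, cfg)
        assert np.all(np.diff(tr1["best_strength"]) >= 0)
        np.testing.assert_array_equal(tr1.values, tr2.values)
        np.testing.assert_array_equal(best1.position, best2.position)

    def test_budget_respected(self, sphere2_bounds):
        fn = CountingStrength(neg_sphere)
        cfg = SOConfig(population_size=20, fe_budget=333, rng_seed=5)
        optimize(fn, sphere2_bounds, cfg)
        assert fn.calls <= 333 + 20

    def test_beats_random_search_on_sphere(self, sphere2_bounds):
        # random-search oracle at equal budget, 20 seeds, >= 18 wins-or-ties
        wins = 0
        for seed in range(20):
            cfg = SOConfig(population_size=50, fe_budget=3000, rng_seed=seed)
            best, _ = optimize(neg_sphere, sphere2_bounds, cfg)
            rng = np.random.default_rng(10_000 + seed)
            samples = rng.uniform(-5, 5, size=(3000, 2))
            rs_best = np.max(-np.sum(samples ** 2, axis=1))
            wins += best.strength >= rs_best
        assert wins >= 18

    def test_non_finite_strength_warns(self, sphere2_bounds):
        def bad(x):
            return np.nan
        cfg = SOConfig(population_size=5, fe_budget=30, rng_seed=0)
        with pytest.warns(UserWarning):
            best, _ = optimize(bad, sphere2_bounds, cfg)
        assert best.strength == -np.inf


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 12),
       d=st.integers(1, 4))
def test_full_cycle_invariants(seed, n, d):
    """Bounds containment, elitism and capacity across complete cycles."""
    b = Bounds(-np.ones(d), np.ones(d))
    cfg = SOConfig(population_size=n, fe_budget=n * 8, rng_seed=seed)
    fn = lambda x: -float(np.sum(np.abs(x)))
    _, trace = optimize(fn, b, cfg)
    assert np.all(np.diff(trace["best_strength"]) >= 0)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_population_and_bounds_each_cycle(seed):
    b = Bounds(np.array([-2.0, -2.0, -2.0]), np.array([2.0, 2.0, 2.0]))
    cfg = SOConfig(population_size=8, fe_budget=200, rng_seed=seed)
    f = init_forest(b, cfg, neg_sphere)
    for _ in range(3):
        renew_phase(f, b, cfg, neg_sphere)
        competition_phase(f, b, cfg, neg_sphere)
        seeding_phase(f, b, cfg, neg_sphere)
        resistance_phase(f, cfg)
        assert len(f) == 8
        for t in f.trees:
            assert b.contains(t.position)


def test_rosenbrock_vs_random_search():
    """Median best over 20 seeds beats equal-budget random search."""
    def neg_rosenbrock(x):
        return -float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)

    b = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
    so_best, rs_best = [], []
    for seed in range(20):
        cfg = SOConfig(population_size=50, fe_budget=3000, rng_seed=seed)
        best, _ = optimize(neg_rosenbrock, b, cfg)
        so_best.append(best.strength)
        rng = np.random.default_rng(20_000 + seed)
        xs = rng.uniform(-5, 5, size=(3000, 2))
        vals = -((1 - xs[:, 0]) ** 2 + 100 * (xs[:, 1] - xs[:, 0] ** 2) ** 2)
        rs_best.append(vals.max())
    assert np.median(so_best) >= np.median(rs_best)


def test_config_yaml_roundtrip(tmp_path):
    import yaml

    from soanfis.so import load_so_config

    path = tmp_path / "so.yaml"
    path.write_text(yaml.safe_dump({"population_size": 12, "fe_budget": 100,
                                    "rng_seed": 3}))
    cfg = load_so_config(path)
    assert cfg.population_size == 12 and cfg.fe_budget == 100


def test_trace_export_csv(tmp_path, sphere2_bounds):
    cfg = SOConfig(population_size=10, fe_budget=100, rng_seed=2)
    _, trace = optimize(neg_sphere, sphere2_bounds, cfg)
    out = tmp_path / "trace.csv"
    trace.to_csv(out, index=False)
    assert out.read_text().startswith("generation,best_strength,fe_used")
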