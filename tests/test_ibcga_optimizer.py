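import numpy as np
import pandas as pd
import pytest

from elene.errors import ConfigError, InvalidChromosomeError
from elene.ibcga_optimizer import (
    Chromosome,
    FitnessEvaluator,
    IBCGAConfig,
    bit_swap_mutation,
    initialize,
    oa_crossover,
    orthogonal_array,
    run,
)
from elene.synthetic_data import TableSpec, generate_table

SMALL_CFG = IBCGAConfig(n_pop=8, g_max=3, r_start=6, r_end=2, cv_folds=3,
                        seed=0)


def make_chrom(n, r, rng, c=0, g=0):
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=r, replace=False)] = True
    return Chromosome(mask, c, g)


class TestOrthogonalArray:
    def test_l8_shape_and_balance(self):
        oa = orthogonal_array(3)
        assert oa.shape == (8, 7)
        assert (oa.sum(axis=0) == 4).all()  # two-level balance

    def test_strength_two(self):
        oa = orthogonal_array(3)
        for i in range(7):
            for j in range(i + 1, 7):
                pairs = list(zip(oa[:, i], oa[:, j]))
                for combo in [(0, 0), (0, 1), (1, 0), (1, 1)]:
                    assert pairs.count(combo) == 2


class TestInitialize:
    def test_popcount_exactly_r_start(self, rng):
        cfg = IBCGAConfig(n_pop=50, r_start=70, r_end=5)
        pop = initialize(cfg, 89, rng)
        assert len(pop) == 50
        assert all(c.popcount == 70 for c in pop)

    def test_seeded_determinism(self):
        cfg = IBCGAConfig(n_pop=10, r_start=5, r_end=2)
        a = initialize(cfg, 20, np.random.default_rng(4))
        b = initialize(cfg, 20, np.random.default_rng(4))
        assert all(x.key() == y.key() for x, y in zip(a, b))

    def test_full_boundary(self, rng):
        cfg = IBCGAConfig(n_pop=3, r_start=70, r_end=5)
        pop = initialize(cfg, 70, rng)
        assert all(c.gene_mask.all() for c in pop)

    def test_r_start_exceeding_n_rejected(self, rng):
        with pytest.raises(ConfigError):
            initialize(IBCGAConfig(r_start=70, r_end=5), 30, rng)


class TestFitness:
    def test_perfectly_separating_feature_reaches_one(self, planted_table):
        ev = FitnessEvaluator(planted_table.frame,
                              IBCGAConfig(cv_folds=5, r_start=3, r_end=1))
        # strong-effect informative columns separate the classes
        mask = np.array([c in planted_table.informative for c in ev.pool])
        fit = ev(Chromosome(mask, c_gene=5, g_gene=5))
        assert fit >= 0.95

    def test_noise_features_near_chance(self):
        pt = generate_table(TableSpec(n_per_class=40, p=10, k=0, effect=0.0,
                                      seed=5))
        ev = FitnessEvaluator(pt.frame, IBCGAConfig(cv_folds=5, r_start=5,
                                                    r_end=2))
        mask = np.zeros(10, dtype=bool)
        mask[:5] = True
        fit = ev(Chromosome(mask, 5, 5))
        assert abs(fit - 1 / 3) < 0.2

    def test_purity_same_chromosome_same_fitness(self, planted_table):
        ev = FitnessEvaluator(planted_table.frame,
                              IBCGAConfig(cv_folds=3, r_start=5, r_end=2))
        ch = make_chrom(30, 5, np.random.default_rng(0))
        assert ev(ch) == ev(Chromosome(ch.gene_mask.copy(), 0, 0))

    def test_zero_features_rejected(self, planted_table):
        ev = FitnessEvaluator(planted_table.frame,
                              IBCGAConfig(cv_folds=3, r_start=5, r_end=2))
        with pytest.raises(InvalidChromosomeError):
            ev(Chromosome(np.zeros(30, dtype=bool), 0, 0))


class TestOACrossover:
    def test_identical_parents_return_copies(self, rng):
        ch = make_chrom(20, 8, rng)
        calls = []
        c1, c2 = oa_crossover(ch, Chromosome(ch.gene_mask.copy(), 0, 0),
                              lambda c: calls.append(1) or 0.5, rng)
        assert not calls  # no evaluations
        assert c1.key() == ch.key()

    def test_children_popcount_preserved(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            r = int(rng.integers(2, n - 1))
            p1 = make_chrom(n, r, rng, c=int(rng.integers(11)))
            p2 = make_chrom(n, r, rng, g=int(rng.integers(10)))
            c1, c2 = oa_crossover(p1, p2, lambda c: float(rng.random()), rng)
            assert c1.popcount == r and c2.popcount == r

    def test_two_factor_toy_problem_child1_is_exhaustive_best(self, rng):
        # parents differ in exactly 2 genes -> 2 single-gene factors; the OA
        # covers all 4 level combinations, so child 1 must match brute force
        n, r = 6, 3
        m1 = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        m2 = np.array([0, 1, 1, 1, 0, 0], dtype=bool)  # differ at genes 0, 3

        def toy_fitness(ch):
            # separable: rewards gene3 on, penalizes gene0 on
            return 1.0 * ch.gene_mask[3] - 0.5 * ch.gene_mask[0]

        best = None
        for lev0 in (0, 1):
            for lev3 in (0, 1):
                mask = m1.copy()
                mask[0] = (m2 if lev0 else m1).gene_mask[0] if False else \
                    [m1, m2][lev0][0]
                mask[3] = [m1, m2][lev3][3]
                if mask.sum() == r:
                    f = 1.0 * mask[3] - 0.5 * mask[0]
                    if best is None or f > best:
                        best = f
        c1, _ = oa_crossover(Chromosome(m1, 0, 0), Chromosome(m2, 0, 0),
                             toy_fitness, rng)
        assert toy_fitness(c1) == best


class TestBitSwap:
    def test_popcount_conserved(self, rng):
        for _ in range(50):
            ch = make_chrom(30, 10, rng)
            assert bit_swap_mutation(ch, rng).popcount == 10

    def test_hamming_distance_two(self, rng):
        ch = make_chrom(30, 10, rng)
        out = bit_swap_mutation(ch, rng, p_m=0.0)
        assert int((out.gene_mask != ch.gene_mask).sum()) == 2

    def test_full_mask_returns_unchanged_with_warning(self, rng):
        ch = Chromosome(np.ones(10, dtype=bool), 0, 0)
        with pytest.warns(UserWarning):
            out = bit_swap_mutation(ch, rng, p_m=0.0)
        assert (out.gene_mask == ch.gene_mask).all()

    def test_unset_positions_uniform(self, rng):
        n, r = 12, 4
        ch = make_chrom(n, r, np.random.default_rng(1))
        unset = np.flatnonzero(~ch.gene_mask)
        counts = {int(i): 0 for i in unset}
        trials = 10_000
        for _ in range(trials):
            out = bit_swap_mutation(ch, rng, p_m=0.0)
            gained = np.flatnonzero(out.gene_mask & ~ch.gene_mask)
            counts[int(gained[0])] += 1
        expected = trials / len(unset)
        sigma = np.sqrt(trials * (1 / len(unset)) * (1 - 1 / len(unset)))
        for c in counts.values():
            assert abs(c - expected) <= 3.5 * sigma


@pytest.fixture(scope="module")
def small_result(planted_table):
    cfg = IBCGAConfig(n_pop=8, g_max=5, r_start=10, r_end=2, cv_folds=3,
                      seed=1)
    return run(cfg, planted_table.frame), cfg


class TestRun:
    def test_m_within_bounds(self, small_result):
        res, cfg = small_result
        assert cfg.r_end <= res.m <= cfg.r_start

    def test_per_r_popcounts_match(self, small_result):
        res, cfg = small_result
        for r, (ch, _) in res.per_r.items():
            assert ch.popcount == r

    def test_determinism_byte_for_byte(self, planted_table):
        cfg = IBCGAConfig(n_pop=6, g_max=2, r_start=5, r_end=3, cv_folds=3,
                          seed=9)
        a = run(cfg, planted_table.frame)
        b = run(cfg, planted_table.frame)
        assert a.best.key() == b.best.key()
        assert a.fitness == b.fitness
        assert a.med_ranking == b.med_ranking

    def test_best_fitness_not_below_initial_population(self, planted_table):
        cfg = IBCGAConfig(n_pop=6, g_max=3, r_start=8, r_end=6, cv_folds=3,
                          seed=2)
        res = run(cfg, planted_table.frame)
        ev = FitnessEvaluator(planted_table.frame, cfg)
        init_best = max(ev(c) for c in
                        initialize(cfg, ev.n, np.random.default_rng(cfg.seed)))
        assert res.fitness >= init_best

    def test_noise_table_m_trends_to_r_end(self):
        pt = generate_table(TableSpec(n_per_class=20, p=12, k=0, effect=0.0,
                                      seed=6))
        ms = []
        for seed in range(10):
            cfg = IBCGAConfig(n_pop=6, g_max=2, r_start=8, r_end=2,
                              cv_folds=3, seed=seed)
            ms.append(run(cfg, pt.frame).m)
        # no fitness gradient rewards extra features: small m dominates
        assert np.median(ms) <= 5

    def test_med_ranking_covers_selected_features(self, small_result):
        res, _ = small_result
        assert sorted(f for f, _ in res.med_ranking) == sorted(res.feature_names)
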