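"""Inheritable bi-objective combinatorial GA for joint feature selection
and SVM hyperparameter tuning.

Each chromosome carries a binary gene per candidate feature plus two index
genes into log2 grids for the SVM cost C and kernel width gamma.  Exactly
``r`` feature genes are set at all times; the loop runs ``G_max``
generations of tournament selection, orthogonal-array crossover and
bit-swap mutation at each ``r`` from ``r_start`` down to ``r_end``,
inheriting the population between phases by unsetting one gene per
individual.  Fitness is stratified-CV accuracy of the decoded SVM, a pure
function of the chromosome within a run (fixed folds, memoized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._svm import C_GRID, GAMMA_GRID, cv_accuracy, make_folds
from .errors import ConfigError, InvalidChromosomeError
from .feature_catalog import feature_columns

__all__ = ["Chromosome", "IBCGAConfig", "FitResult", "FitnessEvaluator",
           "initialize", "oa_crossover", "bit_swap_mutation", "run",
           "orthogonal_array"]


@dataclass(frozen=True)
class Chromosome:
    """Binary feature-selection genes plus encoded SVM (C, gamma)."""

    gene_mask: np.ndarray  # bool, length n
    c_gene: int            # index into the C grid
    g_gene: int            # index into the gamma grid

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_mask",
                           np.asarray(self.gene_mask, dtype=bool))

    @property
    def popcount(self) -> int:
        return int(self.gene_mask.sum())

    def key(self) -> tuple:
        return (self.gene_mask.tobytes(), self.c_gene, self.g_gene)


@dataclass(frozen=True)
class IBCGAConfig:
    n_pop: int = 50
    p_s: float = 1.0
    p_c: float = 0.8
    p_m: float = 0.05
    g_max: int = 100
    r_start: int = 70
    r_end: int = 5
    seed: int = 0
    c_grid: tuple[float, ...] = C_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.r_end <= self.r_start):
            raise ConfigError("need 1 <= r_end <= r_start")
        for p in (self.p_s, self.p_c, self.p_m):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class FitResult:
    """Outcome of one optimizer run."""

    best: Chromosome
    m: int
    fitness: float
    feature_names: tuple[str, ...]       # selected, pool order
    C: float
    gamma: float
    per_r: dict[int, tuple[Chromosome, float]]
    med_ranking: list[tuple[str, float]]  # (feature, main effect difference)
    pool: tuple[str, ...]
    seed: int


class FitnessEvaluator:
    """Memoized CV-accuracy fitness over a fixed feature table."""

    def __init__(self, table: pd.DataFrame, cfg: IBCGAConfig,
                 pool: list[str] | None = None):
        self.pool = tuple(pool) if pool is not None else tuple(feature_columns(table))
        self.X = table[list(self.pool)].to_numpy(dtype=np.float64)
        classes, y = np.unique(table["label"].to_numpy(), return_inverse=True)
        self.classes = classes
        self.y = y
        self.folds = make_folds(y, cfg.cv_folds, cfg.seed)
        self.cfg = cfg
        self._cache: dict[tuple, float] = {}
        self.n_evals = 0

    @property
    def n(self) -> int:
        return len(self.pool)

    def __call__(self, ch: Chromosome) -> float:
        if ch.popcount < 1:
            raise InvalidChromosomeError("chromosome selects zero features")
        k = ch.key()
        hit = self._cache.get(k)
        if hit is not None:
            return hit
        acc = cv_accuracy(self.X[:, ch.gene_mask], self.y, self.folds,
                          self.cfg.c_grid[ch.c_gene],
                          self.cfg.gamma_grid[ch.g_gene])
        self._cache[k] = acc
        self.n_evals += 1
        return acc


def initialize(cfg: IBCGAConfig, n: int,
               rng: np.random.Generator) -> list[Chromosome]:
    """Random population with exactly ``r_start`` genes set per individual."""
    if cfg.r_start > n:
        raise ConfigError(f"r_start={cfg.r_start} exceeds pool size n={n}")
    pop = []
    for _ in range(cfg.n_pop):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=cfg.r_start, replace=False)] = True
        pop.append(Chromosome(mask,
                              int(rng.integers(len(cfg.c_grid))),
                              int(rng.integers(len(cfg.gamma_grid)))))
    return pop


def orthogonal_array(m: int) -> np.ndarray:
    """Two-level OA L(2^m) with 2^m rows and 2^m - 1 columns (0/1 levels).

    Column ``v`` of row ``r`` is the parity of ``r & v`` — the standard
    Hadamard/fractional-factorial construction, strength 2.
    """
    rows = 2 ** m
    cols = rows - 1
    oa = np.zeros((rows, cols), dtype=np.int8)
    for r in range(rows):
        for v in range(1, rows):
            oa[r, v - 1] = bin(r & v).count("1") % 2
    return oa


_L8 = orthogonal_array(3)
_L16 = orthogonal_array(4)


def _repair(mask: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Random bit flips until the mask has exactly ``r`` genes set."""
    mask = mask.copy()
    excess = int(mask.sum()) - r
    if excess > 0:
        on = np.flatnonzero(mask)
        mask[rng.choice(on, size=excess, replace=False)] = False
    elif excess < 0:
        off = np.flatnonzero(~mask)
        mask[rng.choice(off, size=-excess, replace=False)] = True
    return mask


def oa_crossover(p1: Chromosome, p2: Chromosome, fitness_fn,
                 rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Orthogonal-array crossover of two equal-popcount parents.

    Differing gene positions are grouped into contiguous factors (the C
    and gamma genes join as one factor each when they differ); an L8 (L16
    for > 14 differing genes) assigns each factor to a parent per row.
    Every row chromosome is repaired to the parents' popcount and
    evaluated; child 1 is the best row and child 2 the per-factor
    main-effect-predicted combination.
    """
    r = p1.popcount
    if p2.popcount != r:
        raise InvalidChromosomeError("parents must have equal popcount")
    diff = np.flatnonzero(p1.gene_mask != p2.gene_mask)
    param_factors = [name for name, a, b in (
        ("c", p1.c_gene, p2.c_gene), ("g", p1.g_gene, p2.g_gene)) if a != b]
    if len(diff) == 0 and not param_factors:
        return p1, p2

    oa = _L16 if len(diff) > 14 else _L8
    cap = oa.shape[1] if oa is _L16 else 7
    n_gene_factors = min(max(cap - len(param_factors), 1), len(diff))
    gene_groups = (np.array_split(diff, n_gene_factors)
                   if len(diff) else [])
    factors: list[tuple[str, np.ndarray | None]] = \
        [("genes", g) for g in gene_groups if len(g)] + \
        [(nm, None) for nm in param_factors]
    k = len(factors)

    def compose(levels: np.ndarray) -> Chromosome:
        mask = p1.gene_mask.copy()
        c_gene, g_gene = p1.c_gene, p1.g_gene
        for (kind, grp), lev in zip(factors, levels):
            src = p2 if lev else p1
            if kind == "genes":
                mask[grp] = src.gene_mask[grp]
            elif kind == "c":
                c_gene = src.c_gene
            else:
                g_gene = src.g_gene
        return Chromosome(_repair(mask, r, rng), c_gene, g_gene)

    rows = [compose(oa[i, :k]) for i in range(oa.shape[0])]
    fits = np.array([fitness_fn(c) for c in rows])
    child1 = rows[int(np.argmax(fits))]

    best_levels = np.zeros(k, dtype=np.int8)
    for j in range(k):
        lev = oa[:, j]
        if fits[lev == 1].mean() > fits[lev == 0].mean():
            best_levels[j] = 1
    child2 = compose(best_levels)
    return child1, child2


def bit_swap_mutation(ch: Chromosome, rng: np.random.Generator,
                      p_m: float = 0.05, n_c: int = len(C_GRID),
                      n_g: int = len(GAMMA_GRID)) -> Chromosome:
    """Swap one set gene with one unset gene; nudge C/gamma with prob p_m."""
    n = len(ch.gene_mask)
    r = ch.popcount
    c_gene, g_gene = ch.c_gene, ch.g_gene
    if rng.random() < p_m:
        c_gene = int(np.clip(c_gene + rng.choice([-1, 1]), 0, n_c - 1))
    if rng.random() < p_m:
        g_gene = int(np.clip(g_gene + rng.choice([-1, 1]), 0, n_g - 1))
    if r == 0 or r == n:
        warnings.warn("bit-swap impossible (all genes equal); returning unchanged")
        return replace(ch, c_gene=c_gene, g_gene=g_gene)
    mask = ch.gene_mask.copy()
    on = int(rng.choice(np.flatnonzero(mask)))
    off = int(rng.choice(np.flatnonzero(~mask)))
    mask[on], mask[off] = False, True
    return Chromosome(mask, c_gene, g_gene)


def _tournament(pop: list[Chromosome], fits: np.ndarray, size: int,
                rng: np.random.Generator) -> list[Chromosome]:
    """Binary tournament selection of ``size`` individuals."""
    out = []
    for _ in range(size):
        i, j = rng.integers(len(pop), size=2)
        out.append(pop[i] if fits[i] >= fits[j] else pop[j])
    return out


def run(cfg: IBCGAConfig, table: pd.DataFrame,
        pool: list[str] | None = None) -> FitResult:
    """Execute the full inheritable optimization loop (Steps 1-8).

    Returns the best chromosome across all ``r`` phases (ties broken
    toward fewer features) together with the per-phase bests and a
    main-effect-difference ranking of the selected features.
    """
    ev = FitnessEvaluator(table, cfg, pool)
    n = ev.n
    rng = np.random.default_rng(cfg.seed)
    pop = initialize(cfg, n, rng)

    per_r: dict[int, tuple[Chromosome, float]] = {}
    r = cfg.r_start
    while True:
        for _ in range(cfg.g_max):
            fits = np.array([ev(c) for c in pop])
            best_idx = int(np.argmax(fits))
            elite = pop[best_idx]
            elite_fit = fits[best_idx]

            pool_size = max(2, int(round(cfg.p_s * cfg.n_pop)))
            mating = _tournament(pop, fits, pool_size, rng)
            while len(mating) < cfg.n_pop:
                mating.append(elite)
            mating = mating[:cfg.n_pop]

            n_cross = int(round(cfg.p_c * cfg.n_pop)) // 2 * 2
            idx = rng.permutation(cfg.n_pop)[:n_cross]
            for a, b in zip(idx[0::2], idx[1::2]):
                c1, c2 = oa_crossover(mating[a], mating[b], ev, rng)
                mating[a], mating[b] = c1, c2

            new_fits = np.array([ev(c) for c in mating])
            n_mut = int(round(cfg.p_m * cfg.n_pop))
            best_now = int(np.argmax(new_fits))
            candidates = [i for i in range(cfg.n_pop) if i != best_now]
            for i in rng.permutation(candidates)[:n_mut]:
                mating[i] = bit_swap_mutation(mating[i], rng, cfg.p_m,
                                              len(cfg.c_grid),
                                              len(cfg.gamma_grid))

            # elitism: the previous best always survives
            mating_fits = np.array([ev(c) for c in mating])
            if mating_fits.max() < elite_fit:
                mating[int(np.argmin(mating_fits))] = elite
            pop = mating

        fits = np.array([ev(c) for c in pop])
        best_idx = int(np.argmax(fits))
        per_r[r] = (pop[best_idx], float(fits[best_idx]))

        if r <= cfg.r_end:
            break
        # inheritance: unset one random set gene per individual
        pop = [Chromosome(_repair(c.gene_mask, r - 1, rng), c.c_gene, c.g_gene)
               for c in pop]
        r -= 1

    # ties toward smaller m (parsimony)
    best_r = max(per_r, key=lambda rr: (per_r[rr][1], -rr))
    best, best_fit = per_r[best_r]
    selected = tuple(ev.pool[i] for i in np.flatnonzero(best.gene_mask))

    med: list[tuple[str, float]] = []
    if best.popcount > 1:
        for i in np.flatnonzero(best.gene_mask):
            mask = best.gene_mask.copy()
            mask[i] = False
            med.append((ev.pool[i],
                        best_fit - ev(Chromosome(mask, best.c_gene, best.g_gene))))
        med.sort(key=lambda t: -t[1])
    else:
        med = [(selected[0], best_fit)]

    return FitResult(
        best=best, m=best.popcount, fitness=best_fit,
        feature_names=selected,
        C=cfg.c_grid[best.c_gene], gamma=cfg.gamma_grid[best.g_gene],
        per_r=per_r, med_ranking=med, pool=ev.pool, seed=cfg.seed)
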