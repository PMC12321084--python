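"""Stochastic (Gillespie) serial-dilution dynamics with mutation.

Cells are discrete: biomass and nutrients are counted in cell-mass units
(one birth consumes exactly one unit of one nutrient).  Within a batch the
population evolves by an exact birth-only Gillespie process:

* a species sigma is chosen with probability proportional to its total
  uptake rate ``rho_sigma * sum_i j_sigma_i`` with the Monod factors
  evaluated at the current integer nutrient counts;
* the consumed nutrient i is chosen with probability ``j_sigma_i / sum_i
  j_sigma_i`` and decremented by one unit;
* with probability ``nu`` the new daughter cell is a *mutant* whose
  strategy is drawn uniformly at random from a grid of evenly spaced
  strategies (sigma -> sigma + sigma'); otherwise normal growth sigma ->
  2 sigma occurs.  Thus mutation happens at rate ``nu * rho_sigma * sum_i
  j_sigma_i`` and growth at rate ``(1 - nu) * rho_sigma * sum_i j_sigma_i``.

Batches end when every nutrient is exhausted, so each completed batch obeys
the exact bookkeeping identity ``end cells = rho0 cells + c0 cells``.  The
next inoculum is a multinomial sample of ``rho0`` cells from the end-of-batch
composition.  Long runs settle into mutation-selection balance, with the
number of extant strategies fluctuating from batch to batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .batch_dynamics import CommunityState, NutrientState, uptake_rates
from .exceptions import InfeasibleSamplingError, StalledBatchError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyGrid:
    """Evenly spaced two-nutrient strategies: index k -> alpha_1 = k/(n-1)."""

    n_strategies: int = 201

    def __post_init__(self):
        if self.n_strategies < 2:
            raise ValueError("the grid needs at least two strategies")

    @property
    def alphas(self) -> np.ndarray:
        a1 = np.linspace(0.0, 1.0, self.n_strategies)
        return np.column_stack([a1, 1.0 - a1])


@dataclass
class CellPopulation:
    """Integer cell counts per strategy-grid index."""

    counts: np.ndarray
    cell_mass: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total

    def extant_count(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class GillespieConfig:
    """Parameters of a stochastic serial-dilution run.

    Counts and ``K`` share cell-mass units (the reference pairing is an
    inoculum of 1000 cells with K = 1000).
    """

    grid: StrategyGrid = field(default_factory=StrategyGrid)
    mutation_rate: float = 0.01
    c0_cells: int = 1000
    rho0_cells: int = 1000
    K: float = 1000.0
    nutrient_fractions: tuple[float, float] = (0.5, 0.5)
    n_batches: int = 100
    seed: int = 0
    #: Mutant strategies are uniform over the whole grid by default; set a
    #: width w to restrict them to grid indices within +-w of the parent.
    mutation_kernel_width: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation rate must lie in [0, 1)")
        if self.mutation_kernel_width is not None and self.mutation_kernel_width < 1:
            raise ValueError("mutation kernel width must be positive")
        if self.c0_cells < 1 or self.rho0_cells < 1:
            raise ValueError("cell counts must be positive")
        if abs(sum(self.nutrient_fractions) - 1.0) > 1e-12:
            raise ValueError("nutrient fractions must sum to 1")


# ---------------------------------------------------------------------------
# Elementary operations (reference implementations)
# ---------------------------------------------------------------------------

def event_rates(
    population: CellPopulation,
    nutrients: NutrientState,
    nu: float,
    grid: Optional[StrategyGrid] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-strategy growth and mutation rates.

    Growth: ``(1 - nu) * rho_sigma * sum_i j_sigma_i``; mutation:
    ``nu * rho_sigma * sum_i j_sigma_i``.  The two partition the total
    birth rate of each strategy.
    """
    grid = grid or StrategyGrid(population.counts.size)
    community = CommunityState(
        grid.alphas, population.counts.astype(float),
        labels=[f"k{i}" for i in range(population.counts.size)],
    )
    j = uptake_rates(community, nutrients)
    total = population.counts * j.sum(axis=1)
    return (1.0 - nu) * total, nu * total


def gillespie_step(
    population: CellPopulation,
    nutrients: NutrientState,
    nu: float,
    rng: np.random.Generator,
    grid: Optional[StrategyGrid] = None,
    kernel_width: Optional[int] = None,
) -> tuple[CellPopulation, NutrientState, float]:
    """Execute one exact Gillespie event (single-event reference path).

    Returns the updated population and nutrient state plus the exponential
    waiting time of the event.  Raises ``StalledBatchError`` when nutrient
    remains but the total uptake rate is zero.  The batch loop
    (:func:`run_stochastic_batch`) uses a compiled kernel implementing the
    same process.
    """
    grid = grid or StrategyGrid(population.counts.size)
    alphas = grid.alphas
    c = nutrients.concentrations
    monod = c / (nutrients.half_saturation + c)
    j = alphas * monod[np.newaxis, :]          # (n, 2)
    weights = population.counts * j.sum(axis=1)
    total_rate = weights.sum()
    if total_rate <= 0:
        raise StalledBatchError("no positive uptake rate", population)
    wait = rng.exponential(1.0 / total_rate)
    sigma = rng.choice(weights.size, p=weights / total_rate)
    p_nutrient = j[sigma] / j[sigma].sum()
    i = rng.choice(nutrients.p, p=p_nutrient)
    new_c = c.copy()
    new_c[i] -= population.cell_mass
    counts = population.counts.copy()
    if rng.random() < nu:
        if kernel_width is None:
            counts[rng.integers(grid.n_strategies)] += 1
        else:
            lo = max(0, sigma - kernel_width)
            hi = min(grid.n_strategies - 1, sigma + kernel_width)
            counts[rng.integers(lo, hi + 1)] += 1
    else:
        counts[sigma] += 1
    return (
        CellPopulation(counts, population.cell_mass),
        NutrientState(np.maximum(new_c, 0.0), nutrients.half_saturation),
        wait,
    )


# ---------------------------------------------------------------------------
# Compiled batch kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _batch_kernel(counts, a1, a2, c1, c2, K, nu, kernel_width, seed):
    """Run one batch to nutrient exhaustion.  Returns (counts, time, stalled).

    ``kernel_width < 0`` means mutants are uniform over the whole grid;
    otherwise uniform over indices within +-kernel_width of the parent.
    """
    np.random.seed(seed)
    n = counts.size
    t = 0.0
    while c1 > 0 or c2 > 0:
        f1 = c1 / (K + c1) if c1 > 0 else 0.0
        f2 = c2 / (K + c2) if c2 > 0 else 0.0
        total = 0.0
        for k in range(n):
            if counts[k] > 0:
                total += counts[k] * (f1 * a1[k] + f2 * a2[k])
        if total <= 0.0:
            return counts, t, True
        t += -np.log(np.random.random()) / total
        u = np.random.random() * total
        cum = 0.0
        sigma = n - 1
        for k in range(n):
            if counts[k] > 0:
                cum += counts[k] * (f1 * a1[k] + f2 * a2[k])
                if u < cum:
                    sigma = k
                    break
        w1 = f1 * a1[sigma]
        w2 = f2 * a2[sigma]
        if np.random.random() * (w1 + w2) < w1:
            c1 -= 1
        else:
            c2 -= 1
        if nu > 0.0 and np.random.random() < nu:
            if kernel_width < 0:
                counts[np.random.randint(0, n)] += 1
            else:
                lo = max(0, sigma - kernel_width)
                hi = min(n - 1, sigma + kernel_width)
                counts[np.random.randint(lo, hi + 1)] += 1
        else:
            counts[sigma] += 1
    return counts, t, False


def run_stochastic_batch(
    inoculum: CellPopulation,
    config: GillespieConfig,
    seed: int,
) -> tuple[CellPopulation, float]:
    """One stochastic batch: fresh bolus, Gillespie events until exhaustion.

    Nutrients are supplied as integer cell-mass quanta split by
    ``nutrient_fractions`` (rounded so that their sum is exactly
    ``c0_cells``).  Returns the end population and the batch duration.

    Raises ``StalledBatchError`` (carrying the partial population) if the
    total uptake rate reaches zero while nutrient remains; the leftover is
    discarded.
    """
    c1 = int(round(config.c0_cells * config.nutrient_fractions[0]))
    c2 = config.c0_cells - c1
    width = -1 if config.mutation_kernel_width is None else config.mutation_kernel_width
    counts, t, stalled = _batch_kernel(
        inoculum.counts.copy(),
        config.grid.alphas[:, 0].copy(),
        config.grid.alphas[:, 1].copy(),
        c1,
        c2,
        float(config.K),
        float(config.mutation_rate),
        int(width),
        np.uint32(seed),
    )
    population = CellPopulation(counts, inoculum.cell_mass)
    if stalled:
        logger.warning("batch stalled: remaining nutrient discarded")
        raise StalledBatchError("zero total uptake with nutrient remaining", population)
    return population, t


def sample_inoculum(
    end: CellPopulation, rho0_cells: int, rng: np.random.Generator
) -> CellPopulation:
    """Multinomial draw of exactly ``rho0_cells`` cells from the end counts."""
    total = end.total
    if total < rho0_cells:
        raise InfeasibleSamplingError(
            f"end population ({total}) smaller than inoculum ({rho0_cells})"
        )
    counts = rng.multinomial(rho0_cells, end.counts / total)
    return CellPopulation(counts, end.cell_mass)


def run_mutation_selection(
    config: GillespieConfig,
    initial_counts: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Alternate stochastic batches and multinomial bottlenecks.

    The default founding inoculum places all ``rho0_cells`` on the central
    grid strategy (the generalist); under mutation-selection balance the
    founder choice is forgotten after the burn-in.  Returns the
    ``(n_batches, n_strategies)`` array of start-of-batch counts.
    """
    n = config.grid.n_strategies
    if initial_counts is None:
        counts = np.zeros(n, dtype=np.int64)
        counts[n // 2] = config.rho0_cells
    else:
        counts = np.asarray(initial_counts, dtype=np.int64).copy()
        if counts.sum() != config.rho0_cells:
            raise ValueError("initial counts must total rho0_cells")
    ss = np.random.SeedSequence(config.seed)
    batch_seeds = ss.generate_state(config.n_batches, dtype=np.uint32) >> 1
    rng = np.random.default_rng(ss.spawn(1)[0])

    record = np.empty((config.n_batches, n), dtype=np.int64)
    population = CellPopulation(counts)
    for b in range(config.n_batches):
        record[b] = population.counts
        end, _t = run_stochastic_batch(population, config, int(batch_seeds[b]))
        population = sample_inoculum(end, config.rho0_cells, rng)
    return record
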