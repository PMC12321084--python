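"""Deterministic serial-dilution batch dynamics.

A community of ``m`` species competes for ``p`` nutrients in recurring
batches.  Each batch starts with a nutrient bolus of total concentration
``c0`` and an inoculum of total biomass ``rho0``; within the batch species
grow by Monod uptake,

    dc_i/dt   = - sum_sigma rho_sigma j_sigma_i,
    drho_s/dt = rho_sigma sum_i j_sigma_i,

with ``j_sigma_i = c_i / (K + c_i) * alpha_sigma_i``, until the nutrients
are (numerically) exhausted.  The end-of-batch composition, rescaled to
``rho0``, seeds the next batch.  Every species carries a strategy vector of
maximum uptake rates ``alpha`` constrained to a common enzyme budget
``E = sum_i alpha_i`` (1 by convention), so strategies live on a simplex.

In the small-bolus (chemostat-like) limit an arbitrary number of species can
coexist provided the convex hull of their strategies contains the nutrient
supply composition; :func:`hull_contains` implements that predicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

from .exceptions import (
    DegenerateCommunityError,
    DimensionMismatchError,
    NondepletionError,
)

logger = logging.getLogger(__name__)

#: Tolerance on the enzyme-budget constraint sum(alpha) == E.
BUDGET_TOL = 1e-12
#: Boundary tolerance for convex-hull containment (closed hull).
HULL_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyVector:
    """Per-species maximum uptake rates over ``p`` nutrients.

    Parameters
    ----------
    alphas
        Non-negative maximum uptake rate per nutrient (biomass per biomass
        per time).
    budget
        Total enzyme budget ``E``.  When not ``None`` (the default fixes
        ``E = 1``), ``sum(alphas)`` must match it to within ``1e-12``.
        Pass ``None`` for a species whose enzyme pool is dynamic and not
        budget-constrained (the adapter).
    """

    alphas: np.ndarray
    budget: Optional[float] = 1.0

    def __post_init__(self):
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        if self.alphas.ndim != 1:
            raise DimensionMismatchError("alphas must be a 1-D sequence")
        if np.any(self.alphas < 0):
            raise ValueError("uptake rates must be non-negative")
        if self.budget is not None and abs(self.alphas.sum() - self.budget) > BUDGET_TOL:
            raise ValueError(
                f"strategy sums to {self.alphas.sum()!r}, expected budget {self.budget!r}"
            )

    @property
    def p(self) -> int:
        return self.alphas.size


@dataclass(frozen=True)
class NutrientState:
    """Nutrient concentrations ``c_i`` and the shared half-saturation ``K``."""

    concentrations: np.ndarray
    half_saturation: float

    def __post_init__(self):
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if np.any(self.concentrations < 0):
            raise ValueError("nutrient concentrations must be non-negative")
        if self.half_saturation <= 0:
            raise ValueError("half-saturation constant K must be positive")

    @property
    def p(self) -> int:
        return self.concentrations.size


@dataclass
class CommunityState:
    """Per-species biomass densities together with their strategies.

    ``strategies`` is stored as an ``(m, p)`` matrix of uptake rates,
    ``biomass`` as the matching vector of densities ``rho_sigma``, and
    ``labels`` as unique species identifiers.
    """

    strategies: np.ndarray
    biomass: np.ndarray
    labels: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.strategies = np.atleast_2d(np.asarray(self.strategies, dtype=float))
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.strategies.shape[0] != self.biomass.size:
            raise DimensionMismatchError("one strategy row per species required")
        if np.any(self.biomass < 0):
            raise ValueError("biomass densities must be non-negative")
        if self.labels is None:
            self.labels = [f"sp{i}" for i in range(self.biomass.size)]
        self.labels = list(self.labels)
        if len(self.labels) != self.biomass.size:
            raise DimensionMismatchError("one label per species required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("species labels must be unique")

    @classmethod
    def from_strategies(
        cls,
        strategies: Sequence[StrategyVector],
        biomass: Sequence[float],
        labels: Optional[Sequence[str]] = None,
    ) -> "CommunityState":
        mat = np.vstack([s.alphas for s in strategies])
        return cls(mat, np.asarray(biomass, dtype=float), labels)

    @property
    def m(self) -> int:
        return self.biomass.size

    @property
    def p(self) -> int:
        return self.strategies.shape[1]

    @property
    def total_biomass(self) -> float:
        return float(self.biomass.sum())

    @property
    def fractions(self) -> np.ndarray:
        total = self.total_biomass
        if total == 0:
            raise DegenerateCommunityError("total biomass is zero")
        return self.biomass / total


@dataclass(frozen=True)
class BatchConfig:
    """Parameters of one serial-dilution cycle.

    ``c0`` is the total nutrient bolus, split across nutrients according to
    ``nutrient_fractions``; ``rho0`` the inoculum biomass; ``K`` the Monod
    half-saturation.  A batch is declared finished when the total remaining
    nutrient falls below ``depletion_tol * c0`` (exact zero is unreachable
    for Monod kinetics); the residual is discarded at dilution.
    """

    c0: float
    nutrient_fractions: np.ndarray
    rho0: float
    K: float
    depletion_tol: float = 1e-6
    max_time: float = 1e6

    def __post_init__(self):
        object.__setattr__(
            self, "nutrient_fractions", np.asarray(self.nutrient_fractions, dtype=float)
        )
        if abs(self.nutrient_fractions.sum() - 1.0) > 1e-12:
            raise ValueError("nutrient fractions must sum to 1")
        for name in ("c0", "rho0", "K", "depletion_tol", "max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def p(self) -> int:
        return self.nutrient_fractions.size

    def initial_nutrients(self) -> NutrientState:
        return NutrientState(self.c0 * self.nutrient_fractions, self.K)


@dataclass(frozen=True)
class BatchTimecourse:
    """Sampled within-batch trajectory.

    ``times`` is strictly increasing from 0; ``nutrients`` has shape
    ``(len(times), p)`` and ``biomass`` shape ``(len(times), m)``.
    """

    times: np.ndarray
    nutrients: np.ndarray
    biomass: np.ndarray

    def __post_init__(self):
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must strictly increase from 0")
        if len(self.nutrients) != len(self.times) or len(self.biomass) != len(self.times):
            raise DimensionMismatchError("trajectories must match times in length")


# ---------------------------------------------------------------------------
# Within-batch dynamics
# ---------------------------------------------------------------------------

def uptake_rates(community: CommunityState, nutrients: NutrientState) -> np.ndarray:
    """Monod uptake matrix ``j[sigma, i] = c_i/(K + c_i) * alpha_sigma_i``."""
    if community.p != nutrients.p:
        raise DimensionMismatchError(
            f"community has p={community.p} nutrients, environment has p={nutrients.p}"
        )
    c = nutrients.concentrations
    monod = c / (nutrients.half_saturation + c)
    return community.strategies * monod[np.newaxis, :]


def batch_derivatives(
    community: CommunityState, nutrients: NutrientState
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dc/dt, drho/dt)`` of the within-batch dynamics.

    Uptake converts nutrient into biomass one-for-one, so the sum of all
    derivatives vanishes identically (mass conservation).
    """
    j = uptake_rates(community, nutrients)
    dc = -community.biomass @ j
    drho = community.biomass * j.sum(axis=1)
    return dc, drho


def _rhs(t, y, strategies, K, p):
    c = np.maximum(y[:p], 0.0)
    rho = y[p:]
    monod = c / (K + c)
    j = strategies * monod
    dc = -rho @ j
    drho = rho * j.sum(axis=1)
    return np.concatenate((dc, drho))


def run_batch(
    community: CommunityState,
    config: BatchConfig,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[CommunityState, BatchTimecourse]:
    """Integrate one batch from bolus to nutrient depletion.

    The community is seeded with its current biomasses and the fresh bolus
    ``c0 * nutrient_fractions``; integration stops when the total remaining
    nutrient drops below ``depletion_tol * c0``.

    Returns the end-of-batch community and the sampled timecourse.

    Raises
    ------
    NondepletionError
        If the nutrients are not depleted by ``config.max_time``; the
        exception carries the partial timecourse.
    """
    p = config.p
    if community.p != p:
        raise DimensionMismatchError("community and config nutrient dimensions differ")
    c_init = config.c0 * config.nutrient_fractions
    y0 = np.concatenate((c_init, community.biomass))
    threshold = config.depletion_tol * config.c0

    def depleted(t, y, *args):
        return y[:p].sum() - threshold

    depleted.terminal = True
    depleted.direction = -1

    sol = solve_ivp(
        _rhs,
        (0.0, config.max_time),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=depleted,
        args=(community.strategies, config.K, p),
    )
    timecourse = BatchTimecourse(sol.t, sol.y[:p].T, sol.y[p:].T)
    if sol.status != 1:  # no terminal event fired
        raise NondepletionError(
            f"nutrients not depleted by t={config.max_time}", timecourse
        )
    y_end = sol.y[:, -1]
    end = CommunityState(
        community.strategies, np.maximum(y_end[p:], 0.0), community.labels
    )
    return end, timecourse


def dilute(end_community: CommunityState, rho0: float) -> CommunityState:
    """Rescale the end-of-batch composition to total biomass ``rho0``.

    Relative abundances are preserved exactly; residual nutrient is
    discarded by construction.
    """
    total = end_community.total_biomass
    if total <= 0:
        raise DegenerateCommunityError("cannot dilute a community with zero biomass")
    return CommunityState(
        end_community.strategies,
        end_community.biomass * (rho0 / total),
        end_community.labels,
    )


def run_serial(
    community: CommunityState,
    config: BatchConfig,
    max_batches: int,
    ss_tol: float = 1e-8,
    extinction_cutoff: Optional[float] = None,
) -> tuple[pd.DataFrame, Optional[int]]:
    """Run repeated batch-growth/dilution cycles.

    The community is first diluted (or concentrated) to ``rho0`` and then
    carried through ``max_batches`` cycles.  Start-of-batch relative
    abundances are recorded for every batch (batch numbering starts at 1).

    Returns
    -------
    fractions : pandas.DataFrame
        Wide table indexed by batch with one column per species label.
    steady_state_batch : int or None
        First batch ``b`` whose successor inoculum differs by less than
        ``ss_tol`` in L1 norm (``None`` if never reached).  A serial
        steady state is a whole batch timecourse that maps the inoculum
        onto itself.

    By default abundances are never zeroed, however small (the slow decline
    of losing species is itself of interest); pass ``extinction_cutoff`` to
    remove species whose inoculum fraction falls below it at dilution.
    """
    if max_batches < 1:
        raise ValueError("max_batches must be at least 1")
    current = dilute(community, config.rho0)
    rows = [current.fractions.copy()]
    for _ in range(max_batches):
        end, _tc = run_batch(current, config)
        current = dilute(end, config.rho0)
        if extinction_cutoff is not None:
            biomass = current.biomass.copy()
            biomass[current.fractions < extinction_cutoff] = 0.0
            current = dilute(
                CommunityState(current.strategies, biomass, current.labels),
                config.rho0,
            )
        rows.append(current.fractions.copy())
    fracs = np.vstack(rows)
    steady_state_batch = None
    l1 = np.abs(np.diff(fracs, axis=0)).sum(axis=1)
    hits = np.nonzero(l1 < ss_tol)[0]
    if hits.size:
        steady_state_batch = int(hits[0]) + 1
    table = pd.DataFrame(
        fracs[:max_batches], index=pd.RangeIndex(1, max_batches + 1, name="batch"),
        columns=community.labels,
    )
    return table, steady_state_batch


# ---------------------------------------------------------------------------
# Community constructors and the coexistence predicate
# ---------------------------------------------------------------------------

def equally_spaced_community(m: int, p: int = 2) -> list[StrategyVector]:
    """``m`` strategies equally spaced on the two-nutrient simplex.

    Strategy ``k`` has ``alpha_1 = k/(m-1)`` (for ``m == 1`` the single
    strategy is the generalist ``(0.5, 0.5)``), so the endpoints are the two
    pure specialists.  Equal spacing on higher simplices is unsupported.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if p != 2:
        raise DimensionMismatchError("equally spaced strategies require p = 2")
    if m == 1:
        return [StrategyVector(np.array([0.5, 0.5]))]
    a1 = np.linspace(0.0, 1.0, m)
    return [StrategyVector(np.array([a, 1.0 - a])) for a in a1]


def hull_contains(
    strategies: Sequence[StrategyVector], supply_fractions: Sequence[float]
) -> bool:
    """Closed convex-hull coexistence predicate.

    True iff the supply composition, as a point on the ``(p-1)``-simplex,
    lies inside the convex hull of the budget-normalized strategies (within
    a boundary tolerance of ``1e-9``).  In the chemostat limit this is the
    condition for all species to coexist.
    """
    if not strategies:
        raise ValueError("strategies must be nonempty")
    supply = np.asarray(supply_fractions, dtype=float)
    if abs(supply.sum() - 1.0) > 1e-9:
        raise ValueError("supply fractions must sum to 1")
    points = np.vstack([s.alphas / s.alphas.sum() for s in strategies])
    if points.shape[1] != supply.size:
        raise DimensionMismatchError("strategy and supply dimensions differ")
    if supply.size == 2:
        lo, hi = points[:, 0].min(), points[:, 0].max()
        return bool(lo - HULL_TOL <= supply[0] <= hi + HULL_TOL)
    # General p: feasibility LP for supply = sum_k lambda_k * strategy_k,
    # lambda >= 0, sum lambda = 1 (closed hull, small boundary tolerance).
    n = points.shape[0]
    a_eq = np.vstack([points.T, np.ones(n)])
    b_eq = np.concatenate([supply, [1.0]])
    res = linprog(np.zeros(n), A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * n)
    if res.status == 0:
        return True
    # Retry with the boundary slack to classify points on the hull surface.
    res = linprog(
        np.zeros(n),
        A_ub=np.vstack([a_eq, -a_eq]),
        b_ub=np.concatenate([b_eq + HULL_TOL, -(b_eq - HULL_TOL)]),
        bounds=[(0, None)] * n,
    )
    return res.status == 0
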