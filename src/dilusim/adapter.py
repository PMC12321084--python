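"""Enzyme regulation: the adapter species and the invasion protocol.

The adapter is a species whose enzyme allocation has its own dynamics: its
enzyme pool is diluted by growth and replenished by production of one enzyme
at a time, at the per-capita growth rate (each unit of new biomass carries
newly made enzyme, all of the currently selected type),

    d alpha_i / dt = (P_i - alpha_i) * sum_i' j_i',

where ``P_i`` is a one-hot indicator of which enzyme is currently produced.
This form preserves the common enzyme budget: d(sum alpha)/dt =
(1 - sum alpha) * sum j, so sum alpha = E = 1 is an exact invariant and the
adapter's edge over fixed-strategy species is purely one of timing, not of
budget.
For two nutrients the adapter senses the relative concentration difference
``Delta = |c1 - c2| / max(c1, c2)`` and, whenever ``Delta`` exceeds its
sensing threshold ``Delta_c``, redirects production to the enzyme matching
the more abundant nutrient.  This lets it ride the "early-bird" advantage:
consume the abundant nutrient first, then retool for whatever remains —
which is exactly diauxie when the bolus is large.

An invasion experiment lets a resident community reach its serial-dilution
steady state, replaces a fraction of its biomass with an adapter, and tracks
the community over many batches.  The adapter keeps both its enzyme levels
and its production state across batch boundaries.  Outcomes:

* ``TAKEOVER`` — the adapter's inoculum fraction reaches the takeover
  threshold (0.5 by default).  This happens on an emergent timescale much
  longer than the community relaxation time.
* ``LOCKED_COEXISTENCE`` — the community self-organizes so that ``Delta``
  never exceeds ``Delta_c`` within a batch; the adapter stops switching and
  is effectively locked as a fixed-strategy specialist.
* ``UNRESOLVED`` — neither condition met within the simulated horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .batch_dynamics import (
    BatchConfig,
    CommunityState,
    NutrientState,
    StrategyVector,
    dilute,
    equally_spaced_community,
    run_serial,
)
from .exceptions import (
    DimensionMismatchError,
    NondepletionError,
    UndefinedSenseError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdapterSpecies:
    """State of the enzyme-regulating species.

    ``production`` is the indicator vector ``P_i`` — one-hot once the
    adapter has ever sensed a supra-threshold difference, all-zero before
    that (uninitialized sentinel: constitutive production in proportion to
    the current enzyme levels, leaving the strategy frozen, exactly like a
    fixed-strategy species).  ``threshold`` is the sensing tolerance
    ``Delta_c``.
    """

    strategy: StrategyVector
    production: np.ndarray
    threshold: float
    label: str = "adapter"

    def __post_init__(self):
        object.__setattr__(self, "production", np.asarray(self.production, dtype=float))
        if self.production.size != self.strategy.p:
            raise DimensionMismatchError("production indicator must have one entry per nutrient")
        if not set(np.unique(self.production)) <= {0.0, 1.0} or self.production.sum() > 1:
            raise ValueError("production must be one-hot or all-zero")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("sensing threshold must lie in [0, 1]")

    @property
    def producing(self) -> Optional[int]:
        """Index of the enzyme currently produced, or None before first sensing."""
        idx = np.nonzero(self.production)[0]
        return int(idx[0]) if idx.size else None


@dataclass(frozen=True)
class SensedDifference:
    """Relative nutrient difference Delta in [0, 1]."""

    delta: float

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("Delta must lie in [0, 1]")


@dataclass(frozen=True)
class InvasionConfig:
    """Full specification of an adapter-invasion experiment."""

    base: BatchConfig
    threshold: float = 0.02
    invasion_fraction: float = 0.35
    adapter_initial_strategy: StrategyVector = field(
        default_factory=lambda: StrategyVector(np.array([0.5, 0.5]))
    )
    adapter_initial_production: Optional[np.ndarray] = None
    post_invasion_batches: int = 3000
    takeover_threshold: float = 0.5
    lock_window: int = 50
    n_residents: int = 21
    pre_invasion_batches: int = 200
    ss_tol: float = 1e-8
    stop_at_takeover: bool = True

    def __post_init__(self):
        if not 0.0 < self.invasion_fraction < 1.0:
            raise ValueError("invasion fraction must lie in (0, 1)")


@dataclass
class InvasionResult:
    """Per-batch record and classification of one invasion run."""

    fractions: pd.DataFrame          # batch x (residents..., adapter)
    adapter_log: pd.DataFrame        # batch, alpha_i..., production, switches
    outcome: str                     # TAKEOVER / LOCKED_COEXISTENCE / UNRESOLVED
    takeover_batch: Optional[int]    # first post-invasion batch with fraction > 0.5


# ---------------------------------------------------------------------------
# Sensing and regulation
# ---------------------------------------------------------------------------

def relative_difference(nutrients: NutrientState) -> SensedDifference:
    """Relative difference ``Delta = |c1 - c2| / max(c1, c2)`` (p = 2 only)."""
    if nutrients.p != 2:
        raise DimensionMismatchError("the sensing rule is defined for two nutrients")
    c1, c2 = nutrients.concentrations
    top = max(c1, c2)
    if top <= 0:
        raise UndefinedSenseError("both nutrients are zero; Delta is undefined")
    return SensedDifference(abs(c1 - c2) / top)


def update_production(adapter: AdapterSpecies, nutrients: NutrientState) -> AdapterSpecies:
    """Apply the switching rule once.

    If ``Delta`` strictly exceeds the threshold the production indicator
    becomes the one-hot of the more abundant nutrient; otherwise the adapter
    is returned unchanged.
    """
    delta = relative_difference(nutrients).delta
    if delta <= adapter.threshold:
        return adapter
    production = np.zeros(nutrients.p)
    production[int(np.argmax(nutrients.concentrations))] = 1.0
    return replace(adapter, production=production)


def adapter_strategy_derivative(
    adapter: AdapterSpecies, uptake_row: np.ndarray
) -> np.ndarray:
    """``d alpha_i/dt = (P_i - alpha_i) * sum_i' j_i'``.

    Growth dilutes the enzyme pool at the per-capita growth rate while
    production replenishes it at the same total rate, all into the selected
    enzyme; ``sum alpha`` relaxes to 1 and stays there.  Before first
    sensing (all-zero indicator) production is constitutive, proportional
    to the current levels, so the derivative vanishes and the adapter
    behaves exactly like a fixed-strategy species.
    """
    uptake_row = np.asarray(uptake_row, dtype=float)
    if adapter.producing is None:
        return np.zeros_like(adapter.strategy.alphas)
    return (adapter.production - adapter.strategy.alphas) * uptake_row.sum()


def invade(
    community_at_ss: CommunityState, adapter: AdapterSpecies, fraction: float
) -> tuple[CommunityState, float]:
    """Replace ``fraction`` of the community biomass with the adapter.

    Residents are scaled by ``1 - fraction``; the adapter receives
    ``fraction`` of the (unchanged) total biomass.  Returns the scaled
    resident community and the adapter biomass.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("invasion fraction must lie in (0, 1)")
    residents = CommunityState(
        community_at_ss.strategies,
        community_at_ss.biomass * (1.0 - fraction),
        community_at_ss.labels,
    )
    return residents, fraction * community_at_ss.total_biomass


# ---------------------------------------------------------------------------
# Within-batch integration with an adapter
# ---------------------------------------------------------------------------

#: Safety cap on production switches within a single batch; hitting it means
#: the threshold is so small that switching chatters around c1 == c2.
MAX_SWITCHES_PER_BATCH = 1000


def run_adapter_batch(
    residents: CommunityState,
    adapter: AdapterSpecies,
    adapter_biomass: float,
    config: BatchConfig,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    record: bool = False,
) -> tuple[CommunityState, AdapterSpecies, float, int, Optional[pd.DataFrame]]:
    """One batch of the mixed resident + adapter community.

    The adapter's production indicator is piecewise constant; switching is
    resolved by event detection, restarting the integration at each switch:

    * before first sensing (all-zero indicator) the event is a rising
      crossing of ``|c1 - c2| - Delta_c * max(c1, c2)``;
    * while producing enzyme ``i`` the event is a rising crossing of
      ``c_other * (1 - Delta_c) - c_i``, which is exactly the condition
      "the *other* nutrient is more abundant and Delta > Delta_c".

    The rule is also applied once at the start of the batch (the fresh bolus
    may already exceed the threshold).  Returns the end-of-batch residents,
    adapter state (with updated alpha and production), adapter biomass, the
    number of production switches during the batch, and (when ``record``)
    a within-batch trajectory table (t, c_i, rho_sigma, adapter alpha_i).
    """
    p = config.p
    if p != 2:
        raise DimensionMismatchError("the adapter model is defined for two nutrients")
    m = residents.m
    c = config.c0 * config.nutrient_fractions
    adapter = update_production(adapter, NutrientState(c, config.K))
    threshold_mass = config.depletion_tol * config.c0

    strategies = np.vstack([residents.strategies, adapter.strategy.alphas])
    y = np.concatenate((c, residents.biomass, [adapter_biomass], adapter.strategy.alphas))
    t = 0.0
    switches = 0
    dc_tol = adapter.threshold

    def rhs(_t, y):
        c = np.maximum(y[:p], 0.0)
        rho = y[p : p + m + 1]
        alpha = np.maximum(y[p + m + 1 :], 0.0)
        strategies[m] = alpha
        monod = c / (config.K + c)
        j = strategies * monod
        dc = -rho @ j
        drho = rho * j.sum(axis=1)
        if prod_idx is None:  # constitutive: strategy frozen
            dalpha = np.zeros(p)
        else:
            dalpha = (production - alpha) * j[m].sum()
        return np.concatenate((dc, drho, dalpha))

    def depleted(_t, y):
        return y[0] + y[1] - threshold_mass

    depleted.terminal = True
    depleted.direction = -1

    def switch_uninit(_t, y):
        c1, c2 = y[0], y[1]
        return abs(c1 - c2) - dc_tol * max(c1, c2)

    def switch_from(i):
        other = 1 - i

        def event(_t, y):
            return y[other] * (1.0 - dc_tol) - y[i]

        event.terminal = True
        event.direction = 1
        return event

    switch_uninit.terminal = True
    switch_uninit.direction = 1

    segments = [] if record else None
    while True:
        production = adapter.production
        prod_idx = adapter.producing
        switch_event = switch_uninit if prod_idx is None else switch_from(prod_idx)
        sol = solve_ivp(
            rhs,
            (t, config.max_time),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            events=[depleted, switch_event],
        )
        if record:
            segments.append(np.vstack([sol.t, sol.y]).T)
        t = sol.t[-1]
        y = sol.y[:, -1]
        if sol.status != 1:
            raise NondepletionError(f"nutrients not depleted by t={config.max_time}")
        if sol.t_events[0].size:  # depletion fired
            break
        # A switching event fired.  The event geometry guarantees that the
        # more abundant nutrient differs from the current production target
        # (at the crossing Delta == Delta_c exactly, so the strict rule of
        # update_production is resolved here from the event semantics).
        c_now = np.maximum(y[:p], 0.0)
        production = np.zeros(p)
        production[int(np.argmax(c_now))] = 1.0
        adapter = replace(
            adapter,
            strategy=StrategyVector(np.maximum(y[p + m + 1 :], 0.0), budget=None),
            production=production,
        )
        switches += 1
        if switches > MAX_SWITCHES_PER_BATCH:
            raise RuntimeError(
                "production switching chattered beyond "
                f"{MAX_SWITCHES_PER_BATCH} events in one batch"
            )

    end_residents = CommunityState(
        residents.strategies, np.maximum(y[p : p + m], 0.0), residents.labels
    )
    end_adapter = replace(
        adapter, strategy=StrategyVector(np.maximum(y[p + m + 1 :], 0.0), budget=None)
    )
    trajectory = None
    if record:
        data = np.vstack(segments)
        cols = (
            ["t"]
            + [f"c_{i + 1}" for i in range(p)]
            + [f"rho_{lbl}" for lbl in residents.labels]
            + ["rho_adapter", "alpha_1", "alpha_2"]
        )
        trajectory = pd.DataFrame(data, columns=cols)
    return end_residents, end_adapter, float(max(y[p + m], 0.0)), switches, trajectory


# ---------------------------------------------------------------------------
# The invasion experiment
# ---------------------------------------------------------------------------

def run_invasion(config: InvasionConfig) -> InvasionResult:
    """Steady-state community, then adapter invasion, then long-run batches.

    The resident community (``n_residents`` equally spaced strategies, equal
    inocula) is run to its serial-dilution steady state, the adapter replaces
    ``invasion_fraction`` of the inoculum biomass, and the mixed system is
    iterated for up to ``post_invasion_batches`` cycles, recording
    start-of-batch fractions, the adapter's enzyme levels and production
    state, and the number of within-batch switches.
    """
    base = config.base
    strategies = equally_spaced_community(config.n_residents, base.p)
    residents = CommunityState.from_strategies(
        strategies,
        np.full(config.n_residents, base.rho0 / config.n_residents),
    )
    table, ss_batch = run_serial(
        residents, base, config.pre_invasion_batches, config.ss_tol
    )
    if ss_batch is None:
        logger.warning(
            "resident community did not reach steady state in %d batches; "
            "invading the final composition",
            config.pre_invasion_batches,
        )
        ss_batch = config.pre_invasion_batches
    residents = CommunityState(
        residents.strategies,
        base.rho0 * table.loc[ss_batch].to_numpy(),
        residents.labels,
    )

    production = (
        np.zeros(base.p)
        if config.adapter_initial_production is None
        else np.asarray(config.adapter_initial_production, dtype=float)
    )
    adapter = AdapterSpecies(
        StrategyVector(config.adapter_initial_strategy.alphas, budget=None),
        production,
        config.threshold,
    )
    residents, adapter_biomass = invade(residents, adapter, config.invasion_fraction)

    labels = residents.labels + [adapter.label]
    frac_rows, log_rows = [], []
    takeover_batch = None
    lock_run = 0  # consecutive batches with no switch and steady fractions
    prev_fracs = None
    outcome = "UNRESOLVED"

    for batch in range(1, config.post_invasion_batches + 1):
        total = residents.total_biomass + adapter_biomass
        fracs = np.append(residents.biomass, adapter_biomass) / total
        frac_rows.append(fracs)
        log_rows.append(
            (batch, *adapter.strategy.alphas, adapter.producing, 0)
        )
        if takeover_batch is None and fracs[-1] >= config.takeover_threshold:
            takeover_batch = batch
            outcome = "TAKEOVER"
            if config.stop_at_takeover:
                break
        residents_end, adapter, adapter_biomass, switches, _ = run_adapter_batch(
            residents, adapter, adapter_biomass, base
        )
        log_rows[-1] = log_rows[-1][:-1] + (switches,)
        # Dilute the mixed community back to rho0.
        end_total = residents_end.total_biomass + adapter_biomass
        scale = base.rho0 / end_total
        residents = CommunityState(
            residents_end.strategies, residents_end.biomass * scale, residents_end.labels
        )
        adapter_biomass *= scale
        if prev_fracs is not None:
            steady = np.abs(fracs - prev_fracs).sum() < config.ss_tol
            lock_run = lock_run + 1 if (switches == 0 and steady) else 0
        prev_fracs = fracs
        if takeover_batch is None and lock_run >= config.lock_window:
            outcome = "LOCKED_COEXISTENCE"
            break

    fractions = pd.DataFrame(
        frac_rows,
        index=pd.RangeIndex(1, len(frac_rows) + 1, name="batch"),
        columns=labels,
    )
    adapter_log = pd.DataFrame(
        log_rows, columns=["batch", "alpha_1", "alpha_2", "production", "switches"]
    ).set_index("batch")
    return InvasionResult(fractions, adapter_log, outcome, takeover_batch)
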