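"""Event-driven stochastic oracle for the group-state kinetics.

A single cross-bridge group at fixed position x, clamped calcium and fixed
half-sarcomere length is a continuous-time Markov chain on the group-state
graph with rates k*C.  Simulating it with exponential waiting times gives
time-weighted occupancy estimates that must agree with the deterministic
stationary solution — the repository's central cross-check between the
stochastic and ensemble descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .kinetics import RateSystem
from .params import ModelParams


@dataclass
class CTMCResult:
    """Occupancy and transition statistics of one stochastic run."""

    occupancy: np.ndarray          # time-weighted fraction per group state
    occupancy_se: np.ndarray       # standard error (batch means)
    transition_counts: Dict[Tuple[int, int], int]
    n_events: int
    total_time: float              # ms
    seed: int


def ctmc_simulate(
    x: float,
    ca_const: float,
    l: float,
    params: ModelParams,
    n_events: int = 100_000,
    seed: int = 0,
    n_batches: int = 50,
) -> CTMCResult:
    """Gillespie simulation of one group at fixed x, clamped Ca, v = 0.

    Waiting times are exponential with the total exit rate; the next state
    is drawn proportionally to the directed rates k*C.  Occupancy standard
    errors come from batch means over ``n_batches`` contiguous segments.
    Deterministic for a given seed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rs = RateSystem(params, np.array([x]))
    k = rs.rates_clamped(ca_const, l)[:, 0]  # (ne,)
    ns = rs.n_states

    # per-state outgoing edge lists
    out_edges = [[] for _ in range(ns)]
    for e in range(rs.n_edges):
        if k[e] > 0:
            out_edges[rs.edge_a[e]].append((rs.edge_b[e], k[e]))
    targets = [np.array([t for t, _ in lst], dtype=np.int64) for lst in out_edges]
    rates = [np.array([r for _, r in lst]) for lst in out_edges]
    exit_rate = np.array([r.sum() for r in rates])
    cum = [np.cumsum(r) / r.sum() if r.size and r.sum() > 0 else r for r in rates]

    rng = np.random.default_rng(seed)
    state = 0  # all-unbound group
    dwell = np.zeros(ns)
    batch = np.zeros((n_batches, ns))
    counts: Dict[Tuple[int, int], int] = {}
    total = 0.0
    burn_in = n_events // 10  # discard the relaxation from the start state
    events_per_batch = max(1, (n_events - burn_in) // n_batches)

    for ev in range(n_events):
        rate = exit_rate[state]
        if rate <= 0.0:
            # absorbing state: assign all remaining weight to it
            dwell[state] += 1.0
            total += 1.0
            break
        dt = rng.exponential(1.0 / rate)
        if ev >= burn_in:
            dwell[state] += dt
            batch[min((ev - burn_in) // events_per_batch, n_batches - 1), state] += dt
            total += dt
        u = rng.random()
        nxt = targets[state][np.searchsorted(cum[state], u)]
        counts[(state, int(nxt))] = counts.get((state, int(nxt)), 0) + 1
        state = int(nxt)

    occupancy = dwell / total
    bt = batch.sum(axis=1, keepdims=True)
    good = bt[:, 0] > 0
    bfrac = batch[good] / bt[good]
    se = bfrac.std(axis=0, ddof=1) / np.sqrt(good.sum()) if good.sum() > 1 else np.full(
        ns, np.nan
    )
    return CTMCResult(
        occupancy=occupancy,
        occupancy_se=se,
        transition_counts=counts,
        n_events=n_events,
        total_time=total,
        seed=seed,
    )
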