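"""Transition rate construction with guaranteed detailed balance.

Every directed group transition rate factorizes as

    k_AB(x, t) = exp(-(G_beta(x) - G_alpha(x)) / 2RT) * h_AB * f(x) * p(l(t))

where the first factor is the symmetric cross-bridge free-energy part,
``h_AB`` carries the tropomyosin energy change (applied to one direction of
each reversible pair, so that k_AB/k_BA = exp(-dG_total/RT) holds exactly),
``f`` is the fitted position dependence (constant for calcium reactions,
continuous piecewise-linear otherwise) and ``p`` the half-sarcomere-length
dependence.  Calcium enters as a separate bimolecular factor C_AB(t): Ca(t)
on the two association directions, 1 on every other reaction direction, 0
for non-reactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .params import CaTransient, LengthDependence, ModelParams, REACTION_PAIRS
from .states import (
    ADJACENCY,
    STATE_LABELS,
    STATE_INDEX,
    GroupState,
    enumerate_group_states,
    state_energy,
    transition_delta_tm,
    _check_reachable,
)

#: ordered directions receiving the calcium concentration factor
CA_GATED_DIRECTIONS = {("T", "W_Ca"), ("S2", "S2_Ca")}

#: ordered directions to which the tropomyosin factor h is applied
H_DIRECTIONS = {
    ("W_Ca", "T"),
    ("S1_Ca", "W_Ca"),
    ("S2_Ca", "S1_Ca"),
    ("W_Ca", "S2_Ca"),
    ("S2_Ca", "S2"),
    ("T", "S2"),
}

#: unordered pairs whose net flux counts one ATP per completed cycle,
#: with the positive (hydrolysis-completing) detachment direction
ATP_DIRECTIONS = {("S2", "T"), ("S2_Ca", "W_Ca")}

#: length-dependence class per unordered pair
P_KIND = {
    frozenset(("T", "W_Ca")): "L1",
    frozenset(("S2_Ca", "S2")): "L1",
    frozenset(("W_Ca", "S1_Ca")): "L2",
    frozenset(("S1_Ca", "S2_Ca")): "none",
    frozenset(("W_Ca", "S2_Ca")): "none",
    frozenset(("T", "S2")): "none",
}


def _is_reaction(a: str, b: str) -> bool:
    return b in ADJACENCY.get(a, ())


def ca_transient(t, ca: CaTransient):
    """Calcium concentration at time t (ms), arbitrary units.

    (t/T_p)^4 rise to the peak, Gaussian fall exp(-((t-T_p)/T_d)^2) after.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    rising = (t / ca.t_p) ** 4
    falling = np.exp(-(((t - ca.t_p) / ca.t_d) ** 2))
    return ca.amplitude * np.where(t < ca.t_p, rising, falling)


def ca_factor(alpha: str, beta: str, t, ca: CaTransient):
    """Bimolecular calcium factor C for the ordered per-site pair (alpha, beta)."""
    if (alpha, beta) in CA_GATED_DIRECTIONS:
        return ca_transient(t, ca)
    if _is_reaction(alpha, beta):
        return np.ones_like(np.asarray(t, dtype=float))
    return np.zeros_like(np.asarray(t, dtype=float))


def h_factor(A: GroupState, B: GroupState, j: int, tm) -> float:
    """Tropomyosin contribution to the A -> B rate.

    exp(-dU_tm) for the six designated directions (the forward reaction
    carries the full tropomyosin energy change of its product state);
    1 for the opposite directions.
    """
    alpha, beta = _check_reachable(A, B, j)
    if (alpha, beta) not in H_DIRECTIONS:
        return 1.0
    return float(np.exp(-transition_delta_tm(A, j, beta, tm)))


def p_value(pair: Tuple[str, str], l, lengths: LengthDependence):
    """Half-sarcomere-length factor for an unordered reaction pair.

    L1 (calcium reactions): 1 + p_l1*(l_max - l)/(l - l_min), hyperbolic with
    a pole at l_min.  L2 (myosin attachment): exp(p_l2*((l - l_min)/(l_max -
    l_min))^4) + 1.  Others: 1.  Direction-symmetric by construction.
    """
    kind = P_KIND[frozenset(pair)]
    l = np.asarray(l, dtype=float)
    if kind == "L1":
        if np.any(l <= lengths.l_min):
            raise ValueError("l must be > l_min for the L1 length factor")
        return 1.0 + lengths.p_l1 * (lengths.l_max - l) / (l - lengths.l_min)
    if kind == "L2":
        s = (l - lengths.l_min) / (lengths.l_max - lengths.l_min)
        return np.exp(lengths.p_l2 * s ** 4) + 1.0
    return np.ones_like(l)


def build_nodal_positions(pair: Tuple[str, str], profiles, d: float) -> np.ndarray:
    """Sorted nodal x-locations (nm) of the piecewise-linear f for ``pair``.

    Nodes always include the interval boundaries +-d/2.  Additional nodes are
    anchored to the free-energy landscape: the S1_Ca minimum, the crossings
    of the T and S1_Ca profiles, the S2 minimum (x = 0), the crossings of the
    W_Ca and S2-class profiles, and (detachment reaction) the S1 minimum
    shifted by the positive W/S2 crossing.  The node locations move with the
    profiles during fitting; the node *values* are the fitted parameters.
    """
    key = frozenset(pair)
    half = d / 2.0

    def t_s1_roots() -> Tuple[float, float]:
        if profiles.g_s1_min >= 0:
            raise ValueError(
                f"pair {pair}: T and S1_Ca free energies do not intersect "
                "(g_s1_min >= 0)"
            )
        r = np.sqrt(-2.0 * profiles.g_s1_min / profiles.k_s1)
        return profiles.x_s1_min - r, profiles.x_s1_min + r

    def w_s2_root() -> float:
        if profiles.g_w <= profiles.g_s2_min:
            raise ValueError(
                f"pair {pair}: W_Ca and S2 free energies do not intersect "
                "(g_w <= g_s2_min)"
            )
        return float(np.sqrt(2.0 * (profiles.g_w - profiles.g_s2_min) / profiles.k_s2))

    if key == frozenset(("W_Ca", "S1_Ca")):
        lo, hi = t_s1_roots()
        nodes = [-half, lo, profiles.x_s1_min, hi, half]
    elif key in (frozenset(("S1_Ca", "S2_Ca")), frozenset(("W_Ca", "S2_Ca"))):
        _, hi = t_s1_roots()
        nodes = [-half, 0.0, hi, half]
    elif key == frozenset(("T", "S2")):
        w = w_s2_root()
        nodes = [-half, -w, 0.0, w, profiles.x_s1_min + w, half]
    else:
        raise ValueError(f"pair {pair} has no piecewise-linear position factor")

    nodes = np.asarray(nodes, dtype=float)
    if np.any(nodes < -half - 1e-9) or np.any(nodes > half + 1e-9):
        raise ValueError(f"pair {pair}: a nodal point falls outside [-d/2, d/2]")
    order = np.argsort(nodes)
    nodes = nodes[order]
    if np.any(np.diff(nodes) < 1e-9):
        raise ValueError(f"pair {pair}: degenerate (coincident) nodal points")
    return nodes


def f_value(pair: Tuple[str, str], x, params: ModelParams):
    """Position factor f(x) for an unordered pair; clamped at the boundary nodes."""
    x = np.asarray(x, dtype=float)
    half = params.tm.d / 2.0
    if np.any(x < -half - 1e-9) or np.any(x > half + 1e-9):
        raise ValueError("x outside [-d/2, d/2]")
    key = frozenset(pair)
    if key in (frozenset(("T", "W_Ca")), frozenset(("S2_Ca", "S2"))):
        return np.full_like(x, params.rates.f_ca)
    canonical = _canonical_pair(pair)
    nodes = build_nodal_positions(canonical, params.profiles, params.tm.d)
    values = np.asarray(params.rates.f_nodes[canonical], dtype=float)
    if len(values) != len(nodes):
        raise ValueError(
            f"pair {canonical}: {len(values)} node values for {len(nodes)} nodes"
        )
    return np.interp(x, nodes, values)


def _canonical_pair(pair: Tuple[str, str]) -> Tuple[str, str]:
    for p in REACTION_PAIRS:
        if frozenset(p) == frozenset(pair):
            return p
    raise ValueError(f"{pair} is not a reaction of the five-state scheme")


def rate_constant(
    A: GroupState, B: GroupState, j: int, x, t: float, l: float, params: ModelParams
):
    """Directed group transition rate k_AB(x, t) in 1/ms (without the C factor).

    The symmetric factor uses the full thermodynamic force: on the two
    hydrolysis-completing directions (S2 -> T, S2_Ca -> W_Ca) the product
    state is one completed cycle further down, dG_ATP lower (and the reverse
    directions correspondingly higher).
    """
    alpha, beta = _check_reachable(A, B, j)
    x = np.asarray(x, dtype=float)
    dg = state_energy(beta, x, params.profiles) - state_energy(alpha, x, params.profiles)
    if (alpha, beta) in ATP_DIRECTIONS:
        dg = dg - params.dg_atp_rt
    elif (beta, alpha) in ATP_DIRECTIONS:
        dg = dg + params.dg_atp_rt
    sym = np.exp(-0.5 * dg)
    h = h_factor(A, B, j, params.tm)
    f = f_value((alpha, beta), x, params)
    p = p_value((alpha, beta), l, params.lengths)
    return sym * h * f * p


@dataclass
class DirectedEdge:
    """One directed group transition, resolved to array indices."""

    a_idx: int
    b_idx: int
    site: int
    alpha: int  # per-site state index
    beta: int


class RateSystem:
    """Precomputed, vectorized rates of all directed group transitions.

    For a fixed parameter set and position grid, the rate of edge ``e`` at
    grid point ``i`` is ``base[e, i] * p_e(l) * C_e(t)`` where ``base``
    bundles the symmetric free-energy factor, the tropomyosin factor and the
    position factor.  The edge classification (``ca_gated``, ``p_class``)
    lets protocol code assemble the full sparse generator as

        M(t, l) = Ca(t)*p1(l)*M_ca_l1 + p1(l)*M_l1 + p2(l)*M_l2 + M_plain
    """

    def __init__(self, params: ModelParams, x: np.ndarray):
        self.params = params
        self.x = np.asarray(x, dtype=float)
        self.q = params.q
        self.group_states = enumerate_group_states(params.q)
        self.n_states = len(self.group_states)
        self.digits = np.array(
            [[STATE_INDEX[s] for s in gs.sites] for gs in self.group_states],
            dtype=np.int64,
        )
        self._build_edges()
        self._build_base()

    def _build_edges(self) -> None:
        edges: List[DirectedEdge] = []
        h_log: List[float] = []
        for a_idx, gs in enumerate(self.group_states):
            for j, beta_label, B in (
                (j, b, B) for (j, b, B) in _transitions(gs)
            ):
                b_idx = _index_of(B, self.q)
                alpha_label = gs.sites[j]
                edges.append(
                    DirectedEdge(
                        a_idx,
                        b_idx,
                        j,
                        STATE_INDEX[alpha_label],
                        STATE_INDEX[beta_label],
                    )
                )
                if (alpha_label, beta_label) in H_DIRECTIONS:
                    h_log.append(-transition_delta_tm(gs, j, beta_label, self.params.tm))
                else:
                    h_log.append(0.0)
        self.edges = edges
        self.n_edges = len(edges)
        self.edge_a = np.array([e.a_idx for e in edges])
        self.edge_b = np.array([e.b_idx for e in edges])
        self.edge_alpha = np.array([e.alpha for e in edges])
        self.edge_beta = np.array([e.beta for e in edges])
        self._h_log = np.array(h_log)
        pairs = [
            (STATE_LABELS[a], STATE_LABELS[b])
            for a, b in zip(self.edge_alpha, self.edge_beta)
        ]
        self.ca_gated = np.array([p in CA_GATED_DIRECTIONS for p in pairs])
        self.p_class = np.array([P_KIND[frozenset(p)] for p in pairs])
        self.atp_positive = np.array([p in ATP_DIRECTIONS for p in pairs])
        lookup = {(a, b): i for i, (a, b) in enumerate(zip(self.edge_a, self.edge_b))}
        self.rev_index = np.array(
            [lookup[(b, a)] for a, b in zip(self.edge_a, self.edge_b)]
        )
        # chemical drive: +1 on hydrolysis-completing directions, -1 reverse
        rev_atp = {(b, a) for a, b in ATP_DIRECTIONS}
        self.chem_sign = np.array(
            [
                1 if p in ATP_DIRECTIONS else (-1 if p in rev_atp else 0)
                for p in pairs
            ]
        )

    def _build_base(self) -> None:
        prof = self.params.profiles
        g = np.stack([state_energy(s, self.x, prof) for s in STATE_LABELS])  # (5, nx)
        f = np.stack(
            [
                f_value((STATE_LABELS[a], STATE_LABELS[b]), self.x, self.params)
                for a, b in zip(self.edge_alpha, self.edge_beta)
            ]
        )  # (ne, nx)
        dg = g[self.edge_beta] - g[self.edge_alpha]
        # ATP-driven edges: the hydrolysis-completing direction carries the
        # extra free-energy drop dG_ATP (Hill convention), so the symmetric
        # factor uses the full thermodynamic force on those edges.
        drive = 0.5 * self.params.dg_atp_rt * self.chem_sign
        self.base = np.exp(-0.5 * dg + drive[:, None] + self._h_log[:, None]) * f

    # -- evaluation ---------------------------------------------------------

    def p_factors(self, l: float) -> np.ndarray:
        """Per-edge length factor at half-sarcomere length l (um)."""
        out = np.ones(self.n_edges)
        lens = self.params.lengths
        p1 = float(p_value(("T", "W_Ca"), l, lens))
        p2 = float(p_value(("W_Ca", "S1_Ca"), l, lens))
        out[self.p_class == "L1"] = p1
        out[self.p_class == "L2"] = p2
        return out

    def rates(self, t: float, l: float) -> np.ndarray:
        """Full directed rates k*C, shape (n_edges, nx)."""
        c = np.where(self.ca_gated, float(ca_transient(t, self.params.ca)), 1.0)
        return self.base * (self.p_factors(l) * c)[:, None]

    def rates_clamped(self, ca_value: float, l: float) -> np.ndarray:
        """Directed rates k*C at clamped calcium concentration."""
        c = np.where(self.ca_gated, ca_value, 1.0)
        return self.base * (self.p_factors(l) * c)[:, None]

    def generator_at(self, ix: int, ca_value: float, l: float) -> np.ndarray:
        """Dense group-state generator W (n_states x n_states) at grid point ix.

        W[b, a] is the rate a -> b; diagonal holds minus the exit rates, so
        columns sum to zero and dn/dt = W n.
        """
        k = self.rates_clamped(ca_value, l)[:, ix]
        W = np.zeros((self.n_states, self.n_states))
        np.add.at(W, (self.edge_b, self.edge_a), k)
        np.add.at(W, (self.edge_a, self.edge_a), -k)
        return W


def _transitions(gs: GroupState):
    for j, alpha in enumerate(gs.sites):
        for beta in ADJACENCY[alpha]:
            yield j, beta, gs.with_site(j, beta)


def _index_of(gs: GroupState, q: int) -> int:
    k = len(STATE_LABELS)
    out = 0
    for s in gs.sites:
        out = out * k + STATE_INDEX[s]
    return out
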