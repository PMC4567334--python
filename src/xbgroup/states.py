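"""Cross-bridge states, group-state enumeration and free energies.

The five per-site biochemical states of the implemented model are

====== ========== ============== ====================
label  Ca bound   force bearing  tropomyosin position
====== ========== ============== ====================
T      no         no             T (blocked)
W_Ca   yes        no             W (Ca-open)
S1_Ca  yes        yes            S (myosin-shifted)
S2_Ca  yes        yes            S
S2     no         yes            S
====== ========== ============== ====================

A *group state* is the joint state ``A = (alpha_1, ..., alpha_q)`` of ``q``
consecutive cross-bridges coupled by one elastic tropomyosin, flanked by
boundary sites that are permanently in state T.  Group free energy is the
sum of per-site cross-bridge free energies ``G_alpha(x)`` plus the
tropomyosin energy ``U_A`` summed over the ``q + 1`` fragments, which
depends on the group state only, not on ``x``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .params import EnergyProfiles, TropomyosinModel, rt_per_nm_to_pn

#: per-site state labels, in canonical index order
STATE_LABELS: Tuple[str, ...] = ("T", "W_Ca", "S1_Ca", "S2_Ca", "S2")
STATE_INDEX = {s: i for i, s in enumerate(STATE_LABELS)}

CA_BOUND = frozenset({"W_Ca", "S1_Ca", "S2_Ca"})
FORCE_BEARING = frozenset({"S1_Ca", "S2_Ca", "S2"})

#: tropomyosin azimuthal position class occupied in each state
TM_POSITION = {"T": "T", "W_Ca": "W", "S1_Ca": "S", "S2_Ca": "S", "S2": "S"}
TM_CLASSES: Tuple[str, ...] = ("T", "W", "S")

#: the six reversible per-site reactions (adjacency of the five-state scheme)
ADJACENCY = {
    "T": ("W_Ca", "S2"),
    "W_Ca": ("T", "S1_Ca", "S2_Ca"),
    "S1_Ca": ("W_Ca", "S2_Ca"),
    "S2_Ca": ("S1_Ca", "W_Ca", "S2"),
    "S2": ("S2_Ca", "T"),
}


@dataclass(frozen=True)
class XBState:
    """One cross-bridge biochemical state and its derived attributes."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown cross-bridge state {self.label!r}")

    @property
    def ca_bound(self) -> bool:
        return self.label in CA_BOUND

    @property
    def force_bearing(self) -> bool:
        return self.label in FORCE_BEARING

    @property
    def tm_position(self) -> str:
        return TM_POSITION[self.label]


@dataclass(frozen=True)
class GroupState:
    """Ordered tuple of per-site states; boundary neighbors are implicit T.

    Site labels are not restricted to the five-state scheme here, so reduced
    state sets (e.g. the three-state {T, W, S} fixture) can reuse the
    enumeration machinery; operations that need the five-state scheme
    validate labels themselves.
    """

    sites: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("group must contain at least one site")

    @property
    def q(self) -> int:
        return len(self.sites)

    def with_site(self, j: int, new_label: str) -> "GroupState":
        sites = list(self.sites)
        sites[j] = new_label
        return GroupState(tuple(sites))


def enumerate_group_states(
    q: int, per_site_states: Sequence[str] = STATE_LABELS
) -> List[GroupState]:
    """All K^q group states in a stable base-K order.

    Site 0 is the most significant digit, so the index of a state is
    ``sum_k digit_k * K**(q-1-k)`` and lookup is O(1) arithmetic.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not per_site_states:
        raise ValueError("per_site_states must be non-empty")
    return [GroupState(combo) for combo in itertools.product(per_site_states, repeat=q)]


def group_state_index(A: GroupState, per_site_states: Sequence[str] = STATE_LABELS) -> int:
    """Stable index of ``A`` in the :func:`enumerate_group_states` order."""
    idx = {s: i for i, s in enumerate(per_site_states)}
    k = len(per_site_states)
    out = 0
    for s in A.sites:
        out = out * k + idx[s]
    return out


def allowed_transitions(A: GroupState) -> List[Tuple[int, str, GroupState]]:
    """Single-site transitions of the Fig-style five-state scheme.

    Only one cross-bridge may change state per elementary reaction; the
    per-site pair must be one of the six reversible reactions.
    """
    out: List[Tuple[int, str, GroupState]] = []
    for j, alpha in enumerate(A.sites):
        for beta in ADJACENCY[alpha]:
            out.append((j, beta, A.with_site(j, beta)))
    return out


def segment_energy_exact(pos_a: str, pos_b: str, tm: TropomyosinModel) -> float:
    """Exact fragment energy above the relaxed baseline, from geometry (RT).

    Fragment length obeys length^2 = d^2 + displacement^2 and the T->S
    displacement is the sum of the T->W and W->S displacements; the energy
    of a fragment elongated to length ``l`` is U_tr*(l/d - 1)^2... more
    precisely (N_A K_tr / 2)(l - d)^2 = U_tr ((l/d) - 1)^2.
    """
    u = _pair_energy_table(tm)
    key = frozenset((pos_a, pos_b))
    if key == frozenset(("T", "S")):
        u_tr = tm.u_tr

        def disp_over_d(u_seg: float) -> float:
            # (l/d - 1) = sqrt(u_seg/u_tr);  (disp/d)^2 = (l/d)^2 - 1
            r = 1.0 + np.sqrt(u_seg / u_tr)
            return float(np.sqrt(r * r - 1.0))

        disp = disp_over_d(tm.u_tw) + disp_over_d(tm.u_ws)
        l_over_d = np.sqrt(1.0 + disp * disp)
        return float(u_tr * (l_over_d - 1.0) ** 2)
    return u[key]


def _pair_energy_table(tm: TropomyosinModel):
    return {
        frozenset(("T",)): 0.0,
        frozenset(("W",)): 0.0,
        frozenset(("S",)): 0.0,
        frozenset(("T", "W")): tm.u_tw,
        frozenset(("W", "S")): tm.u_ws,
    }


def segment_energy(pos_a: str, pos_b: str, tm: TropomyosinModel) -> float:
    """Tropomyosin fragment energy above the relaxed baseline (RT).

    Symmetric in its arguments; zero for equal positions (no relative
    displacement elongates the fragment).  The T;S energy uses the
    fourth-root combination (u_tw^(1/4) + u_ws^(1/4))^4, the small-energy
    limit of the exact geometric form, accurate to <1% while u_tw, u_ws are
    far below the relaxed baseline energy.
    """
    for p in (pos_a, pos_b):
        if p not in TM_CLASSES:
            raise ValueError(f"unknown tropomyosin position {p!r}")
    key = frozenset((pos_a, pos_b))
    if key == frozenset(("T", "S")):
        return float((tm.u_tw ** 0.25 + tm.u_ws ** 0.25) ** 4)
    return _pair_energy_table(tm)[key]


def _site_positions(A: GroupState) -> List[str]:
    """Tropomyosin positions including the two implicit T boundaries."""
    return ["T"] + [TM_POSITION[s] for s in A.sites] + ["T"]


def group_tm_energy(A: GroupState, tm: TropomyosinModel) -> float:
    """Total tropomyosin energy U_A of the group: sum over q+1 fragments (RT)."""
    pos = _site_positions(A)
    return float(sum(segment_energy(pos[i], pos[i + 1], tm) for i in range(len(pos) - 1)))


def state_energy(label: str, x, profiles: EnergyProfiles):
    """Free energy G_alpha(x) of one per-site state, RT; vectorized in x."""
    x = np.asarray(x, dtype=float)
    if label == "T":
        return np.zeros_like(x)
    if label == "W_Ca":
        return np.full_like(x, profiles.g_w)
    if label == "S1_Ca":
        return profiles.g_s1_min + 0.5 * profiles.k_s1 * (x - profiles.x_s1_min) ** 2
    if label in ("S2_Ca", "S2"):
        return profiles.g_s2_min + 0.5 * profiles.k_s2 * x ** 2
    raise ValueError(f"unknown state {label!r}")


def state_force_rt(label: str, x, profiles: EnergyProfiles):
    """Force dG/dx of one per-site state, RT/nm; zero for T and W_Ca."""
    x = np.asarray(x, dtype=float)
    if label in ("T", "W_Ca"):
        return np.zeros_like(x)
    if label == "S1_Ca":
        return profiles.k_s1 * (x - profiles.x_s1_min)
    if label in ("S2_Ca", "S2"):
        return profiles.k_s2 * x
    raise ValueError(f"unknown state {label!r}")


def state_force(label: str, x, profiles: EnergyProfiles, tm: TropomyosinModel):
    """Force of one per-site state in pN (thermal-energy conversion)."""
    _check_range(x, tm.d)
    return rt_per_nm_to_pn(state_force_rt(label, x, profiles), tm.temperature)


def _check_range(x, d: float) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < -d / 2 - 1e-9) or np.any(x > d / 2 + 1e-9):
        raise ValueError(f"position x outside [-d/2, d/2] = [{-d/2}, {d/2}]")


def group_free_energy(
    A: GroupState, x, profiles: EnergyProfiles, tm: TropomyosinModel
):
    """Group free energy G_A(x) = U_A + sum_i G_{alpha_i}(x), RT.

    All cross-bridges of the group share one position ``x`` (the
    equal-position simplification of the ensemble formalism).
    """
    _check_range(x, tm.d)
    x = np.asarray(x, dtype=float)
    g = np.full_like(x, group_tm_energy(A, tm))
    for s in A.sites:
        g = g + state_energy(s, x, profiles)
    return g


def transition_delta_tm(A: GroupState, j: int, beta: str, tm: TropomyosinModel) -> float:
    """Tropomyosin energy change for the single-site transition A -> B (RT).

    Equals U_{alpha_{j-1};beta} + U_{beta;alpha_{j+1}}
    - U_{alpha_{j-1};alpha_j} - U_{alpha_j;alpha_{j+1}}, with T boundaries.
    """
    pos = _site_positions(A)
    pj = j + 1  # account for left boundary
    old = pos[pj]
    new = TM_POSITION[beta]
    return (
        segment_energy(pos[pj - 1], new, tm)
        + segment_energy(new, pos[pj + 1], tm)
        - segment_energy(pos[pj - 1], old, tm)
        - segment_energy(old, pos[pj + 1], tm)
    )


def transition_delta_G(
    A: GroupState,
    B: GroupState,
    j: int,
    x,
    profiles: EnergyProfiles,
    tm: TropomyosinModel,
):
    """Free-energy difference G_B(x) - G_A(x) for a single-site transition (RT).

    Depends only on the changing site: per-site energy difference plus the
    local tropomyosin fragment rearrangement.  Raises if ``B`` is not
    reachable from ``A`` by changing exactly site ``j`` through one of the
    six reactions.
    """
    alpha, beta = _check_reachable(A, B, j)
    _check_range(x, tm.d)
    x = np.asarray(x, dtype=float)
    dg_site = state_energy(beta, x, profiles) - state_energy(alpha, x, profiles)
    return dg_site + transition_delta_tm(A, j, beta, tm)


def _check_reachable(A: GroupState, B: GroupState, j: int) -> Tuple[str, str]:
    if A.q != B.q:
        raise ValueError("group states differ in size")
    diffs = [k for k in range(A.q) if A.sites[k] != B.sites[k]]
    if diffs != [j]:
        raise ValueError(f"B is not reachable from A by changing site {j} only")
    alpha, beta = A.sites[j], B.sites[j]
    if beta not in ADJACENCY[alpha]:
        raise ValueError(f"({alpha}, {beta}) is not one of the six reactions")
    return alpha, beta
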