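"""Advection-reaction integration of the group-state fractions n_A(x, t).

The equal-position simplification reduces the group-ensemble dynamics to a
1+1-dimensional system: for every group state A, the fraction profile
n_A(x, t) obeys

    dn_A/dt + v(t) dn_A/dx = sum_B (k_BA C_BA n_B - k_AB C_AB n_A)

on one regulatory-unit period x in [-d/2, d/2).  The reaction part is a
linear, stiff, block-diagonal (per grid point) system integrated with the
implicit BDF method using the sparse group-transition Jacobian; advection is
a first-order upwind shift applied in an operator split.  Fractions are
normalized per grid point (sum over A equals 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .kinetics import RateSystem, ca_transient
from .params import ModelParams


@dataclass(frozen=True)
class XGrid:
    """Uniform periodic grid covering one regulatory-unit period.

    Cell-centered: points sit at -d/2 + dx*(i + 1/2), symmetric about the
    origin, so odd force integrands cancel exactly under the periodic
    trapezoid (midpoint) rule.
    """

    n_points: int
    d: float

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")

    @property
    def dx(self) -> float:
        return self.d / self.n_points

    @property
    def x(self) -> np.ndarray:
        return -self.d / 2 + self.dx * (np.arange(self.n_points) + 0.5)


@dataclass
class SolverConfig:
    """Numerical controls for the ensemble integration."""

    dt_out: float = 1.0          # ms, output cadence
    rtol: float = 1e-7
    atol: float = 1e-11
    boundary_policy: str = "periodic"  # or "reset-to-unbound"
    max_drift: float = 1e-8      # normalization guard

    def __post_init__(self) -> None:
        if self.boundary_policy not in ("periodic", "reset-to-unbound"):
            raise ValueError("boundary_policy must be periodic or reset-to-unbound")


class EnsembleDensity:
    """Fractions n_A(x) on the grid; array of shape (n_states, n_points)."""

    def __init__(self, values: np.ndarray, grid: XGrid):
        values = np.asarray(values, dtype=float)
        if values.shape[1] != grid.n_points:
            raise ValueError("density shape does not match grid")
        self.values = values
        self.grid = grid

    def copy(self) -> "EnsembleDensity":
        return EnsembleDensity(self.values.copy(), self.grid)

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def normalize(self, max_drift: float = 1e-8) -> None:
        s = self.column_sums()
        if np.any(np.abs(s - 1.0) > max_drift):
            raise RuntimeError(
                f"normalization drift {np.max(np.abs(s - 1.0)):.3e} exceeds guard"
            )
        self.values /= s[None, :]


def init_density(grid: XGrid, q: int, n_states: Optional[int] = None) -> EnsembleDensity:
    """Diastolic initial condition: all groups fully unbound (all-T) at every x."""
    ns = n_states if n_states is not None else 5 ** q
    values = np.zeros((ns, grid.n_points))
    values[0, :] = 1.0  # index 0 is (T, ..., T) in the canonical order
    return EnsembleDensity(values, grid)


def reaction_step(
    n: EnsembleDensity, rs: RateSystem, t: float, l: float
) -> np.ndarray:
    """Reaction time-derivative sum_B (k_BA C n_B - k_AB C n_A), shape like n.

    Column sums of the result vanish to machine precision (pairwise flux
    cancellation), so the reaction part conserves probability exactly.
    """
    k = rs.rates(t, l)  # (ne, nx)
    flux = k * n.values[rs.edge_a, :]  # flux along each directed edge
    dn = np.zeros_like(n.values)
    np.add.at(dn, rs.edge_b, flux)
    np.add.at(dn, rs.edge_a, -flux)
    return dn


def advect(n: EnsembleDensity, v: float, dt: float, policy: str = "periodic") -> EnsembleDensity:
    """First-order upwind advection of every state profile by v*dt (nm).

    CFL is enforced by internal sub-stepping (|v| dt <= dx per substep).
    Under the periodic policy mass per state is conserved exactly; under
    reset-to-unbound the inflow boundary is fed with fully unbound groups.
    """
    shift = v * dt
    if shift == 0.0:
        return n.copy()
    dx = n.grid.dx
    nsub = max(1, int(np.ceil(abs(shift) / dx)))
    c = shift / (nsub * dx)  # signed Courant number, |c| <= 1
    vals = n.values.copy()
    unbound = np.zeros(vals.shape[0])
    unbound[0] = 1.0
    for _ in range(nsub):
        if c > 0:
            left = np.roll(vals, 1, axis=1)
            if policy == "reset-to-unbound":
                left[:, 0] = unbound
            vals = vals - c * (vals - left)
        else:
            right = np.roll(vals, -1, axis=1)
            if policy == "reset-to-unbound":
                right[:, -1] = unbound
            vals = vals + (-c) * (right - vals)
    return EnsembleDensity(vals, n.grid)


def _build_generator_parts(rs: RateSystem, nx: int):
    """Sparse generator split by time/length dependence class.

    Returns csr matrices (M_ca_l1, M_l1, M_l2, M_plain) over the flattened
    state-major index A*nx + i, so that
    M(t, l) = Ca(t) p1(l) M_ca_l1 + p1(l) M_l1 + p2(l) M_l2 + M_plain.
    """
    parts = {}
    masks = {
        "ca_l1": rs.ca_gated,
        "l1": (~rs.ca_gated) & (rs.p_class == "L1"),
        "l2": rs.p_class == "L2",
        "plain": (~rs.ca_gated) & (rs.p_class == "none"),
    }
    ix = np.arange(nx)
    ntot = rs.n_states * nx
    for name, mask in masks.items():
        e = np.nonzero(mask)[0]
        if len(e) == 0:
            parts[name] = sp.csr_matrix((ntot, ntot))
            continue
        rates = rs.base[e]  # (ne_m, nx)
        rows_gain = (rs.edge_b[e][:, None] * nx + ix[None, :]).ravel()
        cols_gain = (rs.edge_a[e][:, None] * nx + ix[None, :]).ravel()
        rows_loss = cols_gain
        cols_loss = cols_gain
        data = rates.ravel()
        M = sp.coo_matrix(
            (
                np.concatenate([data, -data]),
                (
                    np.concatenate([rows_gain, rows_loss]),
                    np.concatenate([cols_gain, cols_loss]),
                ),
            ),
            shape=(ntot, ntot),
        ).tocsr()
        parts[name] = M
    return parts["ca_l1"], parts["l1"], parts["l2"], parts["plain"]


class ReactionIntegrator:
    """Stiff BDF integration of the reaction system on the full grid."""

    def __init__(self, rs: RateSystem, grid: XGrid, config: SolverConfig):
        self.rs = rs
        self.grid = grid
        self.config = config
        self.parts = _build_generator_parts(rs, grid.n_points)
        self._dense_parts = None
        from .kinetics import p_value

        self._p_value = p_value

    def _dense(self):
        """Per-grid-point dense generator parts, (4, nx, ns, ns)."""
        if self._dense_parts is None:
            rs, nx, ns = self.rs, self.grid.n_points, self.rs.n_states
            masks = {
                0: rs.ca_gated,
                1: (~rs.ca_gated) & (rs.p_class == "L1"),
                2: rs.p_class == "L2",
                3: (~rs.ca_gated) & (rs.p_class == "none"),
            }
            parts = np.zeros((4, nx, ns, ns))
            for k, mask in masks.items():
                e = np.nonzero(mask)[0]
                for i in e:
                    a, b = rs.edge_a[i], rs.edge_b[i]
                    parts[k, :, b, a] += rs.base[i]
                    parts[k, :, a, a] -= rs.base[i]
            self._dense_parts = parts
        return self._dense_parts

    def advance_frozen(
        self, values: np.ndarray, t0: float, t1: float, l_mid: float
    ) -> np.ndarray:
        """Advance by matrix exponentials with coefficients frozen at the
        interval midpoint.

        Exact for the frozen linear system (any stiffness), second-order in
        the coefficient drift — the natural partner of the Strang split used
        for short advection intervals.  Only sensible for modest group-state
        counts; larger systems use the BDF path.
        """
        from scipy.linalg import expm

        ca, p1, p2 = self._coeffs(0.5 * (t0 + t1), l_mid)
        parts = self._dense()
        gen = ca * p1 * parts[0] + p1 * parts[1] + p2 * parts[2] + parts[3]
        dt = t1 - t0
        out = np.empty_like(values)
        for ix in range(self.grid.n_points):
            out[:, ix] = expm(gen[ix] * dt) @ values[:, ix]
        # scaling-and-squaring roundoff on very stiff generators leaves
        # column sums off by ~1e-8; restore exact conservation
        np.clip(out, 0.0, None, out=out)
        sums = out.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise RuntimeError("matrix-exponential step lost probability mass")
        return out / sums[None, :]

    def _coeffs(self, t: float, l: float):
        lens = self.rs.params.lengths
        p1 = float(self._p_value(("T", "W_Ca"), l, lens))
        p2 = float(self._p_value(("W_Ca", "S1_Ca"), l, lens))
        ca = float(ca_transient(t, self.rs.params.ca))
        return ca, p1, p2

    def matrix(self, t: float, l: float) -> sp.csr_matrix:
        ca, p1, p2 = self._coeffs(t, l)
        m_ca, m_l1, m_l2, m_plain = self.parts
        return ca * p1 * m_ca + p1 * m_l1 + p2 * m_l2 + m_plain

    def advance(
        self,
        values: np.ndarray,
        t0: float,
        t1: float,
        l_of_t: Callable[[float], float],
        t_eval: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Integrate reaction only from t0 to t1; returns states at t_eval
        (or just t1), shaped (n_out, n_states, nx)."""
        shape = values.shape

        def rhs(t, y):
            return self.matrix(t, l_of_t(t)).dot(y)

        def jac(t, y):
            return self.matrix(t, l_of_t(t))

        sol = solve_ivp(
            rhs,
            (t0, t1),
            values.ravel(),
            method="BDF",
            jac=jac,
            rtol=self.config.rtol,
            atol=self.config.atol,
            t_eval=t_eval,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"reaction integration failed at t={sol.t[-1]:.3f} ms: {sol.message}"
            )
        return sol.y.T.reshape((-1,) + shape)


def integrate(
    n0: EnsembleDensity,
    t_span: tuple,
    l_of_t: Callable[[float], float],
    v_of_t: Callable[[float], float],
    params: ModelParams,
    config: SolverConfig,
    rs: Optional[RateSystem] = None,
) -> tuple:
    """Operator-split advance over ``t_span``; output at the dt_out cadence.

    ``v_of_t`` is the filament sliding rate in nm/ms (equals the
    half-sarcomere lengthening rate expressed at the cross-bridge scale);
    it is treated as constant within each output interval (Strang split:
    half advection, reaction, half advection).  Returns (times, densities)
    with densities shaped (n_times, n_states, nx), normalized per grid point.
    """
    grid = n0.grid
    if rs is None:
        rs = RateSystem(params, grid.x)
    integ = ReactionIntegrator(rs, grid, config)
    t0, t1 = t_span
    times = [t0]
    n = n0.copy()
    outputs = [n.values.copy()]
    t = t0
    while t < t1 - 1e-12:
        dt = min(config.dt_out, t1 - t)
        v = float(v_of_t(t))
        if v != 0.0:
            n = advect(n, v, dt / 2.0, config.boundary_policy)
        out = integ.advance(n.values, t, t + dt, l_of_t)
        n = EnsembleDensity(out[-1], grid)
        if v != 0.0:
            n = advect(n, v, dt / 2.0, config.boundary_policy)
        n.normalize(config.max_drift)
        np.clip(n.values, 0.0, None, out=n.values)
        t += dt
        times.append(t)
        outputs.append(n.values.copy())
    return np.array(times), np.array(outputs)


def integrate_isometric(
    n0: EnsembleDensity,
    t_span: tuple,
    l: float,
    params: ModelParams,
    config: SolverConfig,
    rs: Optional[RateSystem] = None,
) -> tuple:
    """Fast path for v = 0: a single stiff solve over the whole span."""
    grid = n0.grid
    if rs is None:
        rs = RateSystem(params, grid.x)
    integ = ReactionIntegrator(rs, grid, config)
    t0, t1 = t_span
    n_out = int(round((t1 - t0) / config.dt_out))
    t_eval = t0 + config.dt_out * np.arange(n_out + 1)
    t_eval[-1] = t1
    out = integ.advance(n0.values, t0, t1, lambda t: l, t_eval=t_eval)
    sums = out.sum(axis=1)
    drift = np.max(np.abs(sums - 1.0))
    if drift > config.max_drift * 100:
        raise RuntimeError(f"normalization drift {drift:.3e} in isometric solve")
    out = out / sums[:, None, :]
    return t_eval, np.clip(out, 0.0, None)


def steady_state(
    ca_const: float,
    l: float,
    params: ModelParams,
    grid: XGrid,
    rs: Optional[RateSystem] = None,
) -> EnsembleDensity:
    """Stationary group-state distribution at clamped calcium and v = 0.

    Per grid point, solves the linear balance system with one row replaced
    by the normalization constraint sum_A n_A = 1.  At Ca = 0 the chain is
    reducible (the Ca-gated edges vanish); the unique recurrent class is the
    {T, S2}-only subgraph and the solve returns its stationary law.
    """
    if ca_const < 0:
        raise ValueError("ca_const must be >= 0")
    if rs is None:
        rs = RateSystem(params, grid.x)
    ns = rs.n_states
    out = np.zeros((ns, grid.n_points))
    rhs = np.zeros(ns)
    rhs[-1] = 1.0
    for ix in range(grid.n_points):
        gen = rs.generator_at(ix, ca_const, l)
        W = gen.copy()
        W[-1, :] = 1.0
        sol = None
        try:
            cand = np.linalg.solve(W, rhs)
            if _stationary_ok(gen, cand):
                sol = cand
        except np.linalg.LinAlgError:
            pass
        if sol is None:
            sol = _nullspace_stationary(gen)
        if sol is None:
            # reducible chain (e.g. Ca = 0 with closed pathways): the
            # all-unbound state is the physical absorbing solution
            logging.getLogger(__name__).warning(
                "reducible chain at x=%.2f, Ca=%g: returning all-unbound state",
                grid.x[ix],
                ca_const,
            )
            sol = np.zeros(ns)
            sol[0] = 1.0
        out[:, ix] = np.clip(sol, 0.0, None)
        out[:, ix] /= out[:, ix].sum()
    return EnsembleDensity(out, grid)


def _stationary_ok(gen: np.ndarray, n: np.ndarray, tol: float = 1e-8) -> bool:
    if not np.all(np.isfinite(n)) or n.min() < -1e-6 or abs(n.sum() - 1.0) > 1e-6:
        return False
    scale = np.abs(gen).max(axis=1) + 1e-300
    resid = np.abs(gen @ n) / scale
    return bool(np.max(resid) < tol)


def _nullspace_stationary(gen: np.ndarray) -> Optional[np.ndarray]:
    """Stationary law via SVD nullspace; None if the nullspace is degenerate.

    Columns are pre-scaled to tame the enormous dynamic range of the rates.
    """
    scale = np.abs(gen).max(axis=0)
    scale[scale == 0] = 1.0
    _, s, vt = np.linalg.svd(gen / scale[None, :])
    null_dim = int(np.sum(s < s.max() * 1e-12)) if s.max() > 0 else gen.shape[0]
    if null_dim != 1:
        return None
    v = vt[-1] / scale
    v = np.abs(v)
    total = v.sum()
    if total <= 0 or not np.all(np.isfinite(v)):
        return None
    n = v / total
    return n if _stationary_ok(gen, n, tol=1e-6) else None


def equilibrium_density(
    ca_const: float,
    l: float,
    params: ModelParams,
    grid: XGrid,
    rs: Optional[RateSystem] = None,
) -> EnsembleDensity:
    """Closed-form Boltzmann-with-fugacity stationary law of the UNDRIVEN chain.

    With the ATP drive switched off (dg_atp = 0) every reaction pair
    balances individually and the clamped-Ca stationary distribution is
    n_A(x) proportional to Ca^nu_A exp(-G_A(x)), nu_A the number of
    Ca-bound sites; the length factors p cancel, as they must.  With the
    default driven kinetics the true stationary state is a non-equilibrium
    one, so this closed form serves only as an independent oracle for
    :func:`steady_state` on undriven parameter variants.
    """
    if rs is None:
        rs = RateSystem(params, grid.x)
    from .states import CA_BOUND, STATE_LABELS, group_tm_energy, state_energy

    nu = np.array(
        [sum(STATE_LABELS[d] in CA_BOUND for d in row) for row in rs.digits]
    )
    u_tm = np.array([group_tm_energy(gs, params.tm) for gs in rs.group_states])
    g_site = np.stack(
        [state_energy(s, grid.x, params.profiles) for s in STATE_LABELS]
    )  # (5, nx)
    g_group = u_tm[:, None] + g_site[rs.digits].sum(axis=1)  # (ns, nx)
    if ca_const > 0:
        logw = nu[:, None] * np.log(ca_const) - g_group
        logw -= logw.max(axis=0, keepdims=True)
        w = np.exp(logw)
    else:
        w = np.exp(-g_group) * (nu[:, None] == 0)
    w /= w.sum(axis=0, keepdims=True)
    return EnsembleDensity(w, grid)
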