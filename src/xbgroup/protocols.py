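"""Contraction protocols and tissue-level observables.

Protocols: isometric twitch, afterloaded (physiologic) twitch with an
isometric-isotonic-isometric phase sequence, and clamped-calcium titration.
Observables: Cauchy active stress, per-cross-bridge ATP turnover, stress-
strain area (SSA, the tissue analog of pressure-volume area), contraction
efficiency, force-Ca curves and their Hill slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .kinetics import RateSystem, ca_transient
from .params import K_BOLTZMANN, ModelParams
from .solver import (
    EnsembleDensity,
    ReactionIntegrator,
    SolverConfig,
    XGrid,
    advect,
    init_density,
    integrate_isometric,
    steady_state,
)
from .states import STATE_LABELS, state_force_rt


def diastolic_density(
    params: ModelParams, grid: XGrid, rs: Optional[RateSystem] = None
) -> EnsembleDensity:
    """Resting (diastolic) state: stationary distribution at zero calcium.

    With the ATP drive on the detachment transitions, the zero-calcium
    stationary state is essentially the all-unbound density (strong states
    drain through the driven detachments), so protocol runners start from
    :func:`xbgroup.solver.init_density`; this function returns the exact
    stationary law for reference.
    """
    ca0 = float(ca_transient(0.0, params.ca))
    return steady_state(ca0, 1.05, params, grid, rs)


@dataclass(frozen=True)
class ProtocolSpec:
    """One contraction protocol.

    ``l_ed`` is the end-diastolic half-sarcomere length (um); ``afterload``
    (kPa) applies to afterloaded runs only; ``ca_clamp`` replaces the
    transient for titration runs.
    """

    kind: str = "isometric"          # isometric | afterloaded | ca_clamp
    l_ed: float = 1.05               # um
    afterload: float = 0.0           # kPa
    beat_period: float = 400.0       # ms
    ca_clamp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("isometric", "afterloaded", "ca_clamp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "afterloaded" and self.afterload <= 0:
            raise ValueError("afterload must be positive")


@dataclass
class TwitchResult:
    """Time series and per-beat scalars of one simulated beat."""

    t: np.ndarray                    # ms
    sigma_a: np.ndarray              # kPa
    l: np.ndarray                    # um
    v: np.ndarray                    # um/ms (half-sarcomere lengthening rate)
    v_atp: np.ndarray                # 1/ms per cross-bridge
    atp_per_beat: float = np.nan     # molecules per myosin head
    ssa: float = np.nan              # kJ/m^3
    efficiency: float = np.nan       # dimensionless
    es_point: Tuple[float, float] = (np.nan, np.nan)  # (l_es um, sigma_es kPa)
    densities: Optional[np.ndarray] = None  # (nt, n_states, nx), optional
    phase: Optional[np.ndarray] = None      # per-sample protocol phase labels


def group_force_matrix(rs: RateSystem, x: np.ndarray) -> np.ndarray:
    """Per-group force F_A(x) = sum_i F_{alpha_i}(x) in RT/nm, shape (ns, nx)."""
    prof = rs.params.profiles
    f_site = np.stack([state_force_rt(s, x, prof) for s in STATE_LABELS])
    return f_site[rs.digits].sum(axis=1)


def cauchy_stress(
    n: EnsembleDensity | np.ndarray,
    l: float,
    params: ModelParams,
    rs: RateSystem,
    force_matrix: Optional[np.ndarray] = None,
) -> float:
    """Active Cauchy stress in kPa.

    sigma = prefactor * (1/d) * sum_A int n_A(x) F_A(x) dx, reported per
    cross-bridge (group integrals divided by q so runs at different q are
    comparable).  The prefactor is m*l/2 by default, or m*l under the
    alternative convention (``stress_prefactor_mode``).  Quadrature is the
    trapezoid rule on the periodic grid (sum times dx).
    """
    values = n.values if isinstance(n, EnsembleDensity) else n
    grid_x = rs.x
    dx_m = (grid_x[1] - grid_x[0]) * 1e-9
    if force_matrix is None:
        force_matrix = group_force_matrix(rs, grid_x)
    kt = K_BOLTZMANN * params.tm.temperature  # J
    f_newton = force_matrix * kt / 1e-9
    integral = float((values * f_newton).sum()) * dx_m  # N*m
    d_m = params.tm.d * 1e-9
    m = params.constants.xb_density
    l_m = l * 1e-6
    pref = m * l_m / 2.0 if params.constants.stress_prefactor_mode == "half" else m * l_m
    sigma_pa = pref * integral / d_m / params.q
    return sigma_pa / 1e3


def atp_rate(
    n: EnsembleDensity | np.ndarray, rs: RateSystem, t: float, l: float
) -> float:
    """Per-cross-bridge ATP consumption rate (1/ms).

    Net flux through the hydrolysis-completing detachment directions
    (S2 -> T and S2_Ca -> W_Ca), integrated over x and divided by d and q.
    Positive when the cycle runs in the contraction direction.
    """
    values = n.values if isinstance(n, EnsembleDensity) else n
    k = rs.rates(t, l)
    pos = np.nonzero(rs.atp_positive)[0]
    rev = rs.rev_index[pos]
    net = k[pos] * values[rs.edge_a[pos]] - k[rev] * values[rs.edge_a[rev]]
    dx = rs.x[1] - rs.x[0]
    return float(net.sum()) * dx / rs.params.tm.d / rs.params.q


def atp_per_beat(t: np.ndarray, v_atp: np.ndarray) -> float:
    """Trapezoidal time integral of the ATP rate over one beat."""
    if len(t) < 2:
        raise ValueError("need a full-beat trajectory")
    return float(np.trapezoid(v_atp, t))


def _traces(
    times: np.ndarray,
    densities: np.ndarray,
    l_of_t: Callable[[float], float],
    params: ModelParams,
    rs: RateSystem,
) -> Tuple[np.ndarray, np.ndarray]:
    fmat = group_force_matrix(rs, rs.x)
    sigma = np.empty(len(times))
    vatp = np.empty(len(times))
    for i, (t, nv) in enumerate(zip(times, densities)):
        l = float(l_of_t(t))
        sigma[i] = cauchy_stress(nv, l, params, rs, fmat)
        vatp[i] = atp_rate(nv, rs, t, l)
    return sigma, vatp


def run_isometric(
    spec: ProtocolSpec,
    params: ModelParams,
    grid: Optional[XGrid] = None,
    config: Optional[SolverConfig] = None,
    rs: Optional[RateSystem] = None,
    keep_densities: bool = False,
) -> TwitchResult:
    """One isometric beat: v = 0, l = l_ed, driven by the calcium transient."""
    grid = grid or XGrid(72, params.tm.d)
    config = config or SolverConfig()
    rs = rs or RateSystem(params, grid.x)
    n0 = init_density(grid, params.q, rs.n_states)
    times, dens = integrate_isometric(
        n0, (0.0, spec.beat_period), spec.l_ed, params, config, rs
    )
    sigma, vatp = _traces(times, dens, lambda t: spec.l_ed, params, rs)
    res = TwitchResult(
        t=times,
        sigma_a=sigma,
        l=np.full_like(times, spec.l_ed),
        v=np.zeros_like(times),
        v_atp=vatp,
        densities=dens if keep_densities else None,
    )
    res.atp_per_beat = atp_per_beat(times, vatp)
    res.es_point = (spec.l_ed, float(sigma.max()))
    return res


def run_afterloaded(
    spec: ProtocolSpec,
    params: ModelParams,
    grid: Optional[XGrid] = None,
    config: Optional[SolverConfig] = None,
    rs: Optional[RateSystem] = None,
    stress_tol: float = 0.05,
) -> TwitchResult:
    """Afterloaded (physiologic) twitch.

    Phase sequence: (i) isometric rise at l_ed until the active stress
    reaches the afterload; (ii) isotonic shortening, where for each output
    interval a constant sliding rate v is found by a nonlinear solve so the
    end-of-interval stress equals the afterload (interval quartered on
    solver failure, down to 1/64 ms); (iii) once the solved v re-lengthens
    the sarcomere back to l_ed, the length is clamped there and relaxation
    proceeds isometrically.  The end-systolic point is the point of minimum
    half-sarcomere length.
    """
    from scipy.optimize import brentq

    grid = grid or XGrid(72, params.tm.d)
    if config is None:
        # bound heads dragged past the position window are force-detached
        # (reset-to-unbound inflow) rather than wrapped with reset strain
        config = SolverConfig(boundary_policy="reset-to-unbound")
    rs = rs or RateSystem(params, grid.x)
    integ = ReactionIntegrator(rs, grid, config)
    fmat = group_force_matrix(rs, rs.x)

    dt = config.dt_out
    n_steps = int(round(spec.beat_period / dt))
    n = init_density(grid, params.q, rs.n_states)
    l = spec.l_ed
    t = 0.0
    phase = "isometric_rise"
    times = [0.0]
    sigmas = [cauchy_stress(n, l, params, rs, fmat)]
    lengths = [l]
    vels = [0.0]
    vatps = [atp_rate(n, rs, 0.0, l)]
    phases = ["isometric_rise"]
    v_prev = -1e-3  # nm/ms, initial shortening guess

    # matrix-exponential stepping is exact for the frozen-coefficient linear
    # system and far cheaper than BDF on short intervals for small group
    # spaces; large group spaces keep the sparse BDF path
    use_expm = rs.n_states <= 30

    def react(values, t0, t1, l_const):
        if use_expm:
            return integ.advance_frozen(values, t0, t1, l_const)
        out = integ.advance(values, t0, t1, lambda _: l_const)
        return out[-1]

    def step_with_v(values, t0, dt_step, l0, v_nm_ms):
        """Strang split advance with constant v; returns (values, l_end).

        The interval is sub-split so each advection half-step shifts at most
        one grid cell: dragged cross-bridges must feel the steeply growing
        detachment rates before their strain coordinate travels far, or the
        nearest-site wrap would carry bound heads across the period.
        """
        n_sub = max(1, int(np.ceil(abs(v_nm_ms) * dt_step / grid.dx)))
        sub = dt_step / n_sub
        vals = values.copy()
        l_cur, t_cur = l0, t0
        for _ in range(n_sub):
            l_end = l_cur + v_nm_ms * sub / 1000.0  # nm/ms -> um/ms
            nd = EnsembleDensity(vals, grid)
            if v_nm_ms != 0.0:
                nd = advect(nd, v_nm_ms, sub / 2.0, config.boundary_policy)
            mid_l = 0.5 * (l_cur + l_end)
            vals = react(nd.values, t_cur, t_cur + sub, mid_l)
            nd = EnsembleDensity(vals, grid)
            if v_nm_ms != 0.0:
                nd = advect(nd, v_nm_ms, sub / 2.0, config.boundary_policy)
            nd.normalize(config.max_drift)
            np.clip(nd.values, 0.0, None, out=nd.values)
            vals = nd.values
            l_cur, t_cur = l_end, t_cur + sub
        return vals, l_cur

    v_cap = 8.0  # nm/ms, physiological bound on half-sarcomere sliding rate

    def solve_isotonic(values, t0, dt_step, l0, depth=0):
        """Find constant v over [t0, t0+dt_step] holding end stress at the
        afterload; quarter the interval recursively on failure.

        The rate is searched within a physiological bound; when even maximal
        re-lengthening cannot keep the stress at the afterload (late
        systole), the interval advances at the bound and the phase machine
        soon clamps the length back at l_ed.
        """
        nonlocal v_prev

        # keep the length strictly inside (l_min, l_max]
        v_lo = max(-v_cap, (params.lengths.l_min + 0.02 - l0) * 1000.0 / dt_step)
        v_hi = min(v_cap, (spec.l_ed - l0) * 1000.0 / dt_step + v_cap)

        def mismatch(v_nm_ms):
            vals, l_end = step_with_v(values, t0, dt_step, l0, v_nm_ms)
            return cauchy_stress(vals, l_end, params, rs, fmat) - spec.afterload

        try:
            # directional bracket search from the previous interval's rate:
            # near moderate rates the end-of-interval stress increases with v
            # (lengthening stretches the attached heads), so walk in the
            # direction that reduces the mismatch until the sign flips
            v0 = float(np.clip(v_prev, v_lo, v_hi))
            f0 = mismatch(v0)
            if f0 == 0.0:
                v_sol = v0
            else:
                direction = -1.0 if f0 > 0.0 else 1.0
                step = 0.5
                v_a, f_a = v0, f0
                v_sol = None
                while True:
                    v_b = v_a + direction * step
                    if v_b <= v_lo or v_b >= v_hi:
                        v_b = v_lo if direction < 0 else v_hi
                    f_b = mismatch(v_b)
                    if f_a * f_b < 0.0:
                        lo, hi = sorted((v_a, v_b))
                        v_sol = brentq(mismatch, lo, hi, xtol=1e-6, rtol=1e-10)
                        break
                    if v_b in (v_lo, v_hi):
                        # no admissible rate reaches the afterload: shorten at
                        # the cap if the stress is everywhere above it, else
                        # re-lengthen at the cap (the phase machine clamps at
                        # l_ed shortly after)
                        v_sol = v_lo if f_b > 0.0 else v_hi
                        break
                    v_a, f_a = v_b, f_b
                    step *= 2.0
        except (ValueError, RuntimeError):
            if dt_step <= 1.0 / 64.0 + 1e-12:
                raise RuntimeError(
                    f"isotonic solve exhausted at t={t0:.3f} ms (dt={dt_step:.4f})"
                )
            sub = dt_step / 4.0
            vals, l_cur, t_cur = values, l0, t0
            for _ in range(4):
                vals, l_cur, _ = solve_isotonic(vals, t_cur, sub, l_cur, depth + 1)
                t_cur += sub
            return vals, l_cur, v_prev
        v_prev = v_sol
        vals, l_end = step_with_v(values, t0, dt_step, l0, v_sol)
        return vals, l_end, v_sol

    for _ in range(n_steps):
        if phase == "isometric_rise":
            vals = react(n.values, t, t + dt, l)
            n = EnsembleDensity(vals, grid)
            n.normalize(config.max_drift)
            v_out = 0.0
            sigma_now = cauchy_stress(n, l, params, rs, fmat)
            if sigma_now >= spec.afterload:
                phase = "isotonic"
        elif phase == "isotonic":
            vals, l_new, v_sol = solve_isotonic(n.values, t, dt, l)
            if l_new >= spec.l_ed:
                # re-lengthened back to the end-diastolic length: clamp
                l_new = spec.l_ed
                phase = "isometric_relax"
            n = EnsembleDensity(vals, grid)
            v_out = v_sol / 1000.0  # um/ms
            l = l_new
        else:  # isometric_relax
            vals = react(n.values, t, t + dt, l)
            n = EnsembleDensity(vals, grid)
            n.normalize(config.max_drift)
            v_out = 0.0
        t += dt
        times.append(t)
        lengths.append(l)
        vels.append(v_out)
        sigma_rec = cauchy_stress(n, l, params, rs, fmat)
        sigmas.append(sigma_rec)
        vatps.append(atp_rate(n, rs, t, l))
        if phase == "isotonic" and abs(sigma_rec - spec.afterload) > 0.5:
            # the solve hit the rate cap: the muscle can no longer sustain
            # the afterload and is recoiling toward l_ed
            phases.append("recoil")
        else:
            phases.append(phase)

    times = np.array(times)
    sigmas = np.array(sigmas)
    lengths = np.array(lengths)
    res = TwitchResult(
        t=times,
        sigma_a=sigmas,
        l=lengths,
        v=np.array(vels),
        v_atp=np.array(vatps),
        phase=np.array(phases),
    )
    res.atp_per_beat = atp_per_beat(times, res.v_atp)
    i_es = int(np.argmin(lengths))
    res.es_point = (float(lengths[i_es]), float(sigmas[i_es]))
    return res


# -- end-systolic relation and stress-strain area ---------------------------


def es_line_from_isometric(
    runs: Sequence[TwitchResult],
) -> Callable[[np.ndarray], np.ndarray]:
    """End-systolic stress-length relation from isometric peaks.

    Monotone (PCHIP) interpolation through (l_ed, peak stress) points,
    linearly extrapolated below the smallest length.
    """
    pts = sorted((r.es_point for r in runs), key=lambda p: p[0])
    ls = np.array([p[0] for p in pts])
    ss = np.array([p[1] for p in pts])
    if len(ls) < 2:
        raise ValueError("need at least two isometric runs for the ES line")
    interp = PchipInterpolator(ls, ss, extrapolate=False)
    slope0 = (ss[1] - ss[0]) / (ls[1] - ls[0])
    slope1 = (ss[-1] - ss[-2]) / (ls[-1] - ls[-2])

    def f(l):
        l = np.asarray(l, dtype=float)
        out = interp(l)
        out = np.where(l < ls[0], ss[0] + slope0 * (l - ls[0]), out)
        out = np.where(l > ls[-1], ss[-1] + slope1 * (l - ls[-1]), out)
        return out

    return f


def compute_ssa(
    twitch: TwitchResult,
    es_line: Callable[[np.ndarray], np.ndarray],
    ed_line: Callable[[np.ndarray], np.ndarray] = lambda l: np.zeros_like(
        np.asarray(l, dtype=float)
    ),
) -> float:
    """Stress-strain area of one twitch, kJ/m^3.

    Area in the stress-strain plane bounded by the end-systolic line, the
    end-diastolic line (zero active stress here: passive stress is out of
    scope) and the systolic segment of the trajectory.  Strain is referenced
    to the twitch's end-diastolic length, so kPa times dimensionless strain
    equals kJ/m^3 directly.  The polygon area is evaluated with shapely.
    """
    from shapely.geometry import Polygon

    l_ed = float(twitch.l[0])
    # systolic trajectory from the ED point up to the end-systolic point
    # (minimum length for a shortening beat, peak stress for an isometric one)
    shortened = bool(np.any(twitch.l < l_ed - 1e-12))
    i_es = int(np.argmin(twitch.l)) if shortened else int(np.argmax(twitch.sigma_a))
    l_es = float(twitch.l[i_es])
    # zero crossing of the ES line (left corner of the region)
    l0 = _es_zero_crossing(es_line, l_es)
    ls = np.linspace(l0, l_es, 200)
    upper = np.clip(es_line(ls) - ed_line(ls), 0.0, None)
    traj_l = twitch.l[: i_es + 1]
    traj_s = twitch.sigma_a[: i_es + 1]
    verts = [(l0, 0.0)]
    verts += [(float(a), float(b)) for a, b in zip(ls, upper)]
    verts += [(float(a), float(b)) for a, b in zip(traj_l[::-1], traj_s[::-1])]
    verts += [(l_ed, 0.0)]
    pts = [((l - l_ed) / l_ed, s) for l, s in verts]
    unique = {(round(a, 12), round(b, 12)) for a, b in pts}
    if len(unique) < 3:
        return 0.0  # degenerate region (e.g. coincident ES and ED lines)
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return float(poly.area)


def _es_zero_crossing(es_line, l_start: float) -> float:
    l = l_start
    step = 0.01
    val = float(es_line(l))
    if val <= 0.0:
        return l_start  # degenerate ES line: the bounded region is empty
    for _ in range(200):
        l_next = l - step
        v_next = float(es_line(l_next))
        if v_next <= 0.0:
            # linear root between l_next and l
            return l_next + (l - l_next) * (0.0 - v_next) / (val - v_next)
        l, val = l_next, v_next
    raise RuntimeError("end-systolic line does not reach zero stress")


def efficiency(ssa: float, atp_beat: float, constants) -> float:
    """Contraction efficiency: SSA over the free energy of consumed ATP.

    ssa [kJ/m^3] / (atp_per_beat [per head] * c_myosin [mol/m^3] *
    dG_ATP [kJ/mol]); the Avogadro factors cancel.
    """
    if atp_beat <= 0:
        raise ValueError("atp_per_beat must be positive for efficiency")
    return ssa / (atp_beat * constants.c_myosin * constants.dg_atp)


# -- steady-state force-Ca analysis -----------------------------------------


def force_ca_curve(
    ca_values: np.ndarray,
    l: float,
    params: ModelParams,
    grid: Optional[XGrid] = None,
    rs: Optional[RateSystem] = None,
    plateau: str = "grid",
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized steady-state force versus clamped calcium.

    Returns (ca_values, F_norm) with F_norm the stationary stress normalized
    by the plateau.  ``plateau="grid"`` normalizes by the maximum over the
    evaluated points; ``plateau="anchor"`` normalizes by the stress at a
    deeply saturating concentration (1e4 times the largest requested Ca),
    which avoids the spurious logit blow-up near the top point when the
    requested grid does not fully saturate.
    """
    ca_values = np.asarray(ca_values, dtype=float)
    if np.any(ca_values < 0):
        raise ValueError("calcium values must be non-negative")
    if plateau not in ("grid", "anchor"):
        raise ValueError("plateau must be 'grid' or 'anchor'")
    grid = grid or XGrid(36, params.tm.d)
    rs = rs or RateSystem(params, grid.x)
    fmat = group_force_matrix(rs, rs.x)

    def stress_at(ca: float) -> float:
        return cauchy_stress(steady_state(ca, l, params, grid, rs), l, params, rs, fmat)

    stress = np.array([stress_at(ca) for ca in ca_values])
    if plateau == "anchor":
        norm = stress_at(1e4 * ca_values.max())
    else:
        norm = stress.max()
    if norm <= 0:
        raise RuntimeError("steady-state stress is non-positive at the plateau")
    return ca_values, stress / norm


def hill_slope(
    ca_values: np.ndarray, f_norm: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Hill slope d logit(F_norm) / d log10(Ca) along the force-Ca curve.

    Centered finite differences at interior points, one-sided at the ends;
    points with F_norm outside (0, 1) are excluded.
    """
    ca_values = np.asarray(ca_values, dtype=float)
    f_norm = np.asarray(f_norm, dtype=float)
    ok = (f_norm > 0.0) & (f_norm < 1.0) & (ca_values > 0.0)
    ca, f = ca_values[ok], f_norm[ok]
    if len(ca) < 3:
        raise ValueError("fewer than 3 usable points for the Hill slope")
    y = np.log10(f / (1.0 - f))
    x = np.log10(ca)
    slope = np.gradient(y, x)
    return ca, slope
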