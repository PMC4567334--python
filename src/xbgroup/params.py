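"""Parameter containers for the cross-bridge group-ensemble model.

Internal unit conventions (used everywhere except final observables):
energies in units of RT, positions ``x`` in nm, half-sarcomere length ``l``
in um, time in ms, rates in 1/ms.  Conversions to SI happen only when
computing stress and energetic observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23
#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class TropomyosinModel:
    """Elastic tropomyosin segment energetics.

    A tropomyosin fragment spanning one regulatory unit (length ``d``) is an
    elastic string of stiffness ``k_tr``.  Shifting tropomyosin at one end of
    a fragment (blocked T, Ca-open W or myosin-shifted S azimuthal position)
    elongates the fragment; the energies above the relaxed baseline for the
    two elementary shifts are ``u_tw`` (T;W) and ``u_ws`` (W;S), in RT.
    The relaxed-baseline energy ``u_tr`` is enormous (~3400 RT) but cancels
    in every transition difference, so segment energies are stored relative
    to it.
    """

    u_tw: float = 0.1          # RT
    u_ws: float = 0.05         # RT
    k_tr: float = 21.6         # pN/nm, single-tropomyosin stiffness
    d: float = 36.0            # nm, regulatory-unit length
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        if self.u_tw < 0 or self.u_ws < 0:
            raise ValueError("tropomyosin segment energies must be >= 0")
        if self.k_tr <= 0 or self.d <= 0 or self.temperature <= 0:
            raise ValueError("k_tr, d and temperature must be positive")

    @property
    def kt_pn_nm(self) -> float:
        """Thermal energy in pN*nm (= 1 RT per molecule)."""
        return K_BOLTZMANN * self.temperature * 1e21

    @property
    def u_tr(self) -> float:
        """Relaxed-fragment elastic energy N_A*K_tr*d^2/2, in RT."""
        e_joule = 0.5 * (self.k_tr * 1e-3) * (self.d * 1e-9) ** 2
        return e_joule / (K_BOLTZMANN * self.temperature)


@dataclass(frozen=True)
class EnergyProfiles:
    """Free-energy profiles of the five per-site states, in RT.

    The unbound state T is the reference (G_T = 0).  W_Ca is flat at
    ``g_w``.  The strong-binding states are quadratic: S1_Ca has its minimum
    ``g_s1_min`` at ``x_s1_min`` (relative to the S2 minimum, the model
    origin) with stiffness ``k_s1``; S2_Ca and S2 share one parabola with
    minimum ``g_s2_min`` at x = 0 and stiffness ``k_s2`` (the Ca-binding
    free-energy difference is carried by the calcium factor).
    """

    g_w: float = -0.8        # RT
    g_s1_min: float = -3.0   # RT
    x_s1_min: float = 8.5    # nm
    k_s1: float = 0.2        # RT/nm^2
    g_s2_min: float = -17.0  # RT
    k_s2: float = 0.4        # RT/nm^2

    def __post_init__(self) -> None:
        if self.k_s1 <= 0 or self.k_s2 <= 0:
            raise ValueError("quadratic stiffnesses must be positive")


@dataclass(frozen=True)
class CaTransient:
    """Intracellular calcium transient shape (arbitrary concentration units).

    Rising phase (t/T_p)^4 up to the peak at ``t_p``, Gaussian decay with
    characteristic time ``t_d`` afterwards; continuous at the peak.
    """

    t_p: float = 35.0        # ms, time to peak
    t_d: float = 80.0        # ms, characteristic decay time
    amplitude: float = 1.0   # a.u.

    def __post_init__(self) -> None:
        if self.t_p <= 0 or self.t_d <= 0:
            raise ValueError("t_p and t_d must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class LengthDependence:
    """Half-sarcomere length range and length-sensitivity parameters.

    ``p_l1`` enters the hyperbolic factor applied to both calcium
    association/dissociation reactions; ``p_l2`` the quartic-exponential
    factor applied to myosin attachment (W_Ca <-> S1_Ca).  Both factors are
    direction-symmetric, so they change kinetics, never equilibria.
    """

    l_min: float = 0.8   # um
    l_max: float = 1.1   # um
    p_l1: float = 0.24
    p_l2: float = 4.08

    def __post_init__(self) -> None:
        if not self.l_min < self.l_max:
            raise ValueError("l_min must be < l_max")


# Unordered per-site reaction pairs of the five-state scheme.
REACTION_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("T", "W_Ca"),
    ("W_Ca", "S1_Ca"),
    ("S1_Ca", "S2_Ca"),
    ("W_Ca", "S2_Ca"),
    ("S2_Ca", "S2"),
    ("T", "S2"),
)

#: pairs whose position factor f is a single shared constant (Ca on/off)
CONSTANT_F_PAIRS = frozenset({("T", "W_Ca"), ("S2_Ca", "S2")})


@dataclass(frozen=True)
class ReactionRates:
    """Fitted rate-magnitude parameters (1/ms).

    ``f_ca`` is the shared constant position factor of the two calcium
    binding/unbinding reactions.  ``f_nodes`` maps each of the four
    attachment/stroke/detachment pairs to the nodal values of its continuous
    piecewise-linear position factor; the nodal x-locations are derived from
    the free-energy profiles (see :func:`xbgroup.kinetics.build_nodal_positions`)
    and are not stored here.
    """

    f_ca: float = 0.162
    f_nodes: Dict[Tuple[str, str], Tuple[float, ...]] = field(
        default_factory=lambda: {
            # 5 nodes: -d/2, lower T/S1 crossing, S1 minimum, upper crossing,
            # d/2.  Zero below the lower crossing: myosin only attaches where
            # the bound state is energetically available, which localizes
            # force generation at positive strain.  The small magnitudes make
            # attachment rate-limiting at short sarcomere lengths, where the
            # length factor p_L2 is weak -- the source of the length
            # dependence of peak twitch stress.
            ("W_Ca", "S1_Ca"): (0.0, 0.0, 9.44e-3, 4.11e-3, 1.9e-4),
            # 4 nodes: -d/2, S2 minimum (0), upper T/S1 crossing, d/2
            ("S1_Ca", "S2_Ca"): (0.003, 0.3, 0.36, 0.03),
            # the two detachment reactions carry the ATP free-energy drop
            # exp(+dG_ATP/2RT) ~ 1e5, so their position factors are of order
            # 1e-5 to give physiological detachment rates
            ("W_Ca", "S2_Ca"): (0.0, 4.4e-6, 1.47e-5, 4.4e-6),
            # 6 nodes: -d/2, -w, 0, +w, x1+w, d/2   (w: W/S2 crossing)
            ("T", "S2"): (7.2e-5, 7.2e-5, 7.2e-5, 7.2e-5, 2.41e-5, 1.2e-5),
        }
    )

    def __post_init__(self) -> None:
        if self.f_ca < 0:
            raise ValueError("f_ca must be >= 0")
        for pair, vals in self.f_nodes.items():
            if any(v < 0 for v in vals):
                raise ValueError(f"negative f node value for pair {pair}")


@dataclass(frozen=True)
class MechanicsConstants:
    """Constants converting per-cross-bridge quantities to tissue level."""

    c_myosin: float = 0.18          # mol/m^3, myosin ATPase concentration
    dg_atp: float = 60.0            # kJ/mol, ATP hydrolysis free energy
    m: float | None = None          # cross-bridges per m^3; default c_myosin*N_A
    stress_prefactor_mode: str = "half"  # "half" (m*l/2d) or "full" (m*l/d)

    def __post_init__(self) -> None:
        if self.stress_prefactor_mode not in ("half", "full"):
            raise ValueError("stress_prefactor_mode must be 'half' or 'full'")

    @property
    def xb_density(self) -> float:
        """Cross-bridge number density (1/m^3)."""
        return self.m if self.m is not None else self.c_myosin * N_AVOGADRO


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the five-state group-ensemble model."""

    q: int = 3
    tm: TropomyosinModel = field(default_factory=TropomyosinModel)
    profiles: EnergyProfiles = field(default_factory=EnergyProfiles)
    ca: CaTransient = field(default_factory=CaTransient)
    lengths: LengthDependence = field(default_factory=LengthDependence)
    rates: ReactionRates = field(default_factory=ReactionRates)
    constants: MechanicsConstants = field(default_factory=MechanicsConstants)
    beat_period: float = 400.0  # ms

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.beat_period <= 0:
            raise ValueError("beat_period must be positive")

    @property
    def dg_atp_rt(self) -> float:
        """ATP hydrolysis free energy in RT units at the model temperature.

        Carried by the cycle-completing detachment transitions (Hill
        convention): the hydrolysis-completing direction of the two
        ATP-counted reactions is boosted by exp(+dG_ATP/2RT) and its
        reverse suppressed symmetrically, so each completed cycle
        dissipates one ATP free energy.
        """
        r_gas = 8.31446261815324  # J/mol/K
        return self.constants.dg_atp * 1e3 / (r_gas * self.tm.temperature)

    def with_q(self, q: int) -> "ModelParams":
        return replace(self, q=q)

    def with_tm_energies(self, u_tw: float, u_ws: float) -> "ModelParams":
        return replace(self, tm=replace(self.tm, u_tw=u_tw, u_ws=u_ws))


def rt_per_nm_to_pn(force_rt_nm: float | np.ndarray, temperature: float) -> np.ndarray:
    """Convert a force from RT/nm to pN at the given temperature."""
    return np.asarray(force_rt_nm) * K_BOLTZMANN * temperature * 1e21
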