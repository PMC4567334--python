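"""Synthetic twitch datasets emulating the experimental fitting targets.

The fitting machinery targets isometric stress transients of thin cardiac
muscle preparations at several end-diastolic half-sarcomere lengths
(0.95-1.1 um), end-systolic stress-length points and per-beat SSA/ATP
pairs.  No such dataset ships with the package, so this module generates
one from the forward model at known parameters, optionally with additive
Gaussian measurement noise — giving fitting tests a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import ModelParams
from .protocols import (
    ProtocolSpec,
    TwitchResult,
    compute_ssa,
    es_line_from_isometric,
    run_afterloaded,
    run_isometric,
)
from .solver import SolverConfig, XGrid


@dataclass
class FitDataset:
    """Measurement records consumed by the fitting residuals.

    ``isometric_traces`` holds (l um, t ms, stress kPa) samples;
    ``es_points`` the end-systolic stress-length relation of the isometric
    runs; ``afterloads`` the afterload levels (kPa) of the physiologic runs.
    """

    isometric_traces: pd.DataFrame          # columns: l, t, stress
    es_points: List[Tuple[float, float]]    # (l um, sigma kPa)
    afterloads: List[float]                 # kPa
    l_ed_afterloaded: float = 1.05          # um

    @property
    def n_isom(self) -> int:
        return len(self.isometric_traces)

    @property
    def n_isot(self) -> int:
        return len(self.afterloads)

    @property
    def lengths(self) -> List[float]:
        return sorted(self.isometric_traces["l"].unique().tolist())


@dataclass
class SyntheticDataset(FitDataset):
    """A FitDataset with recorded provenance (generator inputs)."""

    noise_sd: float = 0.0
    seed: int = 0
    true_params: Optional[ModelParams] = None


def generate_twitch_dataset(
    params: ModelParams,
    lengths: Sequence[float] = (0.95, 1.0, 1.05, 1.1),
    afterloads: Sequence[float] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    cadence: float = 5.0,
    grid: Optional[XGrid] = None,
    config: Optional[SolverConfig] = None,
) -> SyntheticDataset:
    """Forward-model dataset at the given conditions.

    Isometric beats are run at each length and sampled at the given cadence
    (ms); independent Gaussian noise of sd ``noise_sd`` (kPa) is added to
    the stress samples.  End-systolic points are the per-length peak
    stresses of the noiseless traces.  ``noise_sd = 0`` reproduces the
    forward model exactly.
    """
    rng = np.random.default_rng(seed)
    grid = grid or XGrid(36, params.tm.d)
    rows = []
    es_points = []
    for l_ed in lengths:
        res = run_isometric(ProtocolSpec(l_ed=l_ed), params, grid=grid, config=config)
        mask = np.isclose(res.t % cadence, 0.0) | np.isclose(res.t % cadence, cadence)
        t_s = res.t[mask]
        s_s = res.sigma_a[mask]
        if noise_sd > 0:
            s_s = s_s + rng.normal(0.0, noise_sd, size=s_s.shape)
        for t, s in zip(t_s, s_s):
            rows.append((l_ed, float(t), float(s)))
        es_points.append(res.es_point)
    traces = pd.DataFrame(rows, columns=["l", "t", "stress"])
    return SyntheticDataset(
        isometric_traces=traces,
        es_points=es_points,
        afterloads=list(afterloads),
        noise_sd=noise_sd,
        seed=seed,
        true_params=params,
    )


def default_params(q: int = 3) -> ModelParams:
    """The package's reference parameter set.

    Measured constants (regulatory-unit length d = 36 nm, tropomyosin
    stiffness 21.6 pN/nm, the fitted segment energies U_TW = 0.1 RT and
    U_WS = 0.05 RT, the length window 0.8-1.1 um, myosin 0.18 mol/m^3,
    ATP free energy 60 kJ/mol) are literature values; everything else
    (free-energy profile depths and stiffnesses, rate nodal values,
    calcium-transient times) is a package fixture calibrated once to give
    a physiological isometric twitch (peak stress in the tens of kPa at
    l_ed = 1.05 um, relaxation within the beat, contraction efficiency in
    the experimental 60-70% band).  See the emitted config for the
    per-value fixture/literature labels.
    """
    return ModelParams(q=q)


def describe_params(params: ModelParams) -> Dict[str, Dict]:
    """Parameter dictionary with units and fixture/literature provenance labels."""
    tm, prof, ca, lens, rates, const = (
        params.tm,
        params.profiles,
        params.ca,
        params.lengths,
        params.rates,
        params.constants,
    )

    def entry(value, unit, source):
        return {"value": value, "unit": unit, "source": source}

    return {
        "q": entry(params.q, "-", "protocol choice"),
        "d": entry(tm.d, "nm", "literature"),
        "K_tr": entry(tm.k_tr, "pN/nm", "literature"),
        "U_TW": entry(tm.u_tw, "RT", "literature (fitted value)"),
        "U_WS": entry(tm.u_ws, "RT", "literature (fitted value)"),
        "temperature": entry(tm.temperature, "K", "literature"),
        "G_W": entry(prof.g_w, "RT", "fixture"),
        "G_S1_min": entry(prof.g_s1_min, "RT", "fixture"),
        "x_S1_min": entry(prof.x_s1_min, "nm", "fixture"),
        "K_S1": entry(prof.k_s1, "RT/nm^2", "fixture"),
        "G_S2_min": entry(prof.g_s2_min, "RT", "fixture"),
        "K_S2": entry(prof.k_s2, "RT/nm^2", "fixture"),
        "T_p": entry(ca.t_p, "ms", "fixture"),
        "T_d": entry(ca.t_d, "ms", "fixture"),
        "ca_amplitude": entry(ca.amplitude, "a.u.", "convention"),
        "l_min": entry(lens.l_min, "um", "literature"),
        "l_max": entry(lens.l_max, "um", "literature"),
        "p_L1": entry(lens.p_l1, "-", "fixture"),
        "p_L2": entry(lens.p_l2, "-", "fixture"),
        "f_ca": entry(rates.f_ca, "1/ms", "fixture"),
        "f_nodes": {
            "-".join(pair): entry(list(v), "1/ms", "fixture")
            for pair, v in rates.f_nodes.items()
        },
        "c_myosin": entry(const.c_myosin, "mol/m^3", "literature"),
        "dG_ATP": entry(const.dg_atp, "kJ/mol", "literature"),
        "beat_period": entry(params.beat_period, "ms", "fixture"),
    }


def random_params(rng: np.random.Generator, q: int = 1, coupled: bool = False) -> ModelParams:
    """A random but physically valid parameter set from the fixture family.

    Profiles are drawn so that all rate nodal-point intersections exist
    inside the position window; rate node values are positive and of the
    same physiological magnitude class as the reference fixture.  Used by
    property tests and the acceptance analysis as "the model with randomized
    parameters".
    """
    from .params import (
        CaTransient,
        EnergyProfiles,
        LengthDependence,
        ReactionRates,
        TropomyosinModel,
    )

    base = default_params(q=q)
    for _ in range(200):
        g_w = rng.uniform(-1.5, 0.5)
        g_s1 = rng.uniform(-4.0, -1.5)
        x1 = rng.uniform(5.0, 9.0)
        k_s1 = rng.uniform(0.12, 0.3)
        g_s2 = rng.uniform(-18.0, -10.0)
        k_s2 = rng.uniform(0.25, 0.45)
        prof = EnergyProfiles(
            g_w=g_w, g_s1_min=g_s1, x_s1_min=x1, k_s1=k_s1, g_s2_min=g_s2, k_s2=k_s2
        )
        d = base.tm.d
        w = np.sqrt(2.0 * (g_w - g_s2) / k_s2)
        r = np.sqrt(-2.0 * g_s1 / k_s1)
        if w < d / 2 and x1 + w < d / 2 and x1 + r < d / 2 and x1 - r > -d / 2:
            break
    else:  # pragma: no cover - parameter box is chosen to make this unreachable
        raise RuntimeError("could not draw valid profiles")

    def pos(n, scale):
        return tuple(rng.uniform(0.2, 1.0, size=n) * scale)

    w1 = 10 ** rng.uniform(-3.0, -1.7)
    w2 = 10 ** rng.uniform(-5.7, -4.7)
    t2 = 10 ** rng.uniform(-4.7, -3.7)
    rates = ReactionRates(
        f_ca=rng.uniform(0.04, 0.16),
        f_nodes={
            ("W_Ca", "S1_Ca"): (0.0, 0.0) + pos(2, w1) + (0.02 * w1,),
            ("S1_Ca", "S2_Ca"): (0.003,) + pos(2, rng.uniform(0.15, 0.45)) + (0.02,),
            ("W_Ca", "S2_Ca"): (0.0,) + pos(2, w2) + (0.3 * w2,),
            ("T", "S2"): pos(6, t2),
        },
    )
    if coupled:
        tm = TropomyosinModel(u_tw=rng.uniform(0.05, 1.0), u_ws=rng.uniform(0.05, 1.0))
    else:
        tm = TropomyosinModel(u_tw=0.0, u_ws=0.0)
    return ModelParams(
        q=q,
        tm=tm,
        profiles=prof,
        ca=CaTransient(),
        lengths=LengthDependence(
            p_l1=rng.uniform(0.0, 1.5), p_l2=rng.uniform(0.0, 6.0)
        ),
        rates=rates,
    )
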