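"""Config schema, validation and result serialization.

Runs are described by a single YAML or JSON document with model, solver,
protocol and constants blocks.  The schema is validated strictly (unknown
keys rejected) before any computation, and every run emits a provenance
record (config hash, package version, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .params import (
    CaTransient,
    EnergyProfiles,
    LengthDependence,
    MechanicsConstants,
    ModelParams,
    ReactionRates,
    TropomyosinModel,
)

_PAIR_KEYS = {
    "W_Ca-S1_Ca": ("W_Ca", "S1_Ca"),
    "S1_Ca-S2_Ca": ("S1_Ca", "S2_Ca"),
    "W_Ca-S2_Ca": ("W_Ca", "S2_Ca"),
    "T-S2": ("T", "S2"),
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TropomyosinBlock(_Strict):
    u_tw: float = Field(0.1, ge=0, description="RT")
    u_ws: float = Field(0.05, ge=0, description="RT")
    k_tr: float = Field(21.6, gt=0, description="pN/nm")
    d: float = Field(36.0, gt=0, description="nm")
    temperature: float = Field(310.0, gt=0, description="K")


class ProfilesBlock(_Strict):
    g_w: float = Field(default_factory=lambda: EnergyProfiles().g_w)
    g_s1_min: float = Field(default_factory=lambda: EnergyProfiles().g_s1_min)
    x_s1_min: float = Field(default_factory=lambda: EnergyProfiles().x_s1_min)
    k_s1: float = Field(default_factory=lambda: EnergyProfiles().k_s1, gt=0)
    g_s2_min: float = Field(default_factory=lambda: EnergyProfiles().g_s2_min)
    k_s2: float = Field(default_factory=lambda: EnergyProfiles().k_s2, gt=0)


class CaBlock(_Strict):
    t_p: float = Field(default_factory=lambda: CaTransient().t_p, gt=0, description="ms")
    t_d: float = Field(default_factory=lambda: CaTransient().t_d, gt=0, description="ms")
    amplitude: float = Field(1.0, ge=0)


class LengthBlock(_Strict):
    l_min: float = Field(0.8, description="um")
    l_max: float = Field(1.1, description="um")
    p_l1: float = Field(default_factory=lambda: LengthDependence().p_l1)
    p_l2: float = Field(default_factory=lambda: LengthDependence().p_l2)


class RatesBlock(_Strict):
    f_ca: float = Field(default_factory=lambda: ReactionRates().f_ca, ge=0)
    f_nodes: Dict[str, List[float]] = Field(
        default_factory=lambda: {
            "-".join(k): list(v) for k, v in ReactionRates().f_nodes.items()
        }
    )

    @field_validator("f_nodes")
    @classmethod
    def _check_pairs(cls, v):
        for key, vals in v.items():
            if key not in _PAIR_KEYS:
                raise ValueError(f"unknown reaction pair {key!r}")
            if any(x < 0 for x in vals):
                raise ValueError(f"negative node value for {key!r}")
        return v


class ConstantsBlock(_Strict):
    c_myosin: float = Field(0.18, gt=0, description="mol/m^3")
    dg_atp: float = Field(60.0, gt=0, description="kJ/mol")
    m: Optional[float] = Field(None, gt=0, description="1/m^3")
    stress_prefactor_mode: Literal["half", "full"] = "half"


class ModelBlock(_Strict):
    q: int = Field(3, ge=1)
    beat_period: float = Field(400.0, gt=0, description="ms")
    tropomyosin: TropomyosinBlock = TropomyosinBlock()
    profiles: ProfilesBlock = ProfilesBlock()
    ca: CaBlock = CaBlock()
    lengths: LengthBlock = LengthBlock()
    rates: RatesBlock = RatesBlock()
    constants: ConstantsBlock = ConstantsBlock()


class SolverBlock(_Strict):
    n_points: int = Field(72, ge=16)
    dt_out: float = Field(1.0, gt=0, description="ms")
    rtol: float = Field(1e-7, gt=0)
    atol: float = Field(1e-11, gt=0)
    boundary_policy: Literal["periodic", "reset-to-unbound"] = "periodic"


class ProtocolBlock(_Strict):
    kind: Literal["isometric", "afterloaded", "ca_clamp"] = "isometric"
    l_ed: float = Field(1.05, description="um")
    afterload: float = Field(0.0, ge=0, description="kPa")
    ca_clamp: Optional[float] = Field(None, ge=0)
    lengths: Optional[List[float]] = None          # sweep for isometric
    afterloads: Optional[List[float]] = None       # sweep for afterloaded
    ca_values: Optional[List[float]] = None        # titration grid


class OutputBlock(_Strict):
    directory: str = "out"
    write_traces: bool = True
    verbosity: int = Field(1, ge=0, le=2)


class RunConfig(_Strict):
    model: ModelBlock = ModelBlock()
    solver: SolverBlock = SolverBlock()
    protocol: ProtocolBlock = ProtocolBlock()
    output: OutputBlock = OutputBlock()
    seed: int = 0

    def to_model_params(self) -> ModelParams:
        m = self.model
        return ModelParams(
            q=m.q,
            tm=TropomyosinModel(
                u_tw=m.tropomyosin.u_tw,
                u_ws=m.tropomyosin.u_ws,
                k_tr=m.tropomyosin.k_tr,
                d=m.tropomyosin.d,
                temperature=m.tropomyosin.temperature,
            ),
            profiles=EnergyProfiles(**m.profiles.model_dump()),
            ca=CaTransient(t_p=m.ca.t_p, t_d=m.ca.t_d, amplitude=m.ca.amplitude),
            lengths=LengthDependence(**m.lengths.model_dump()),
            rates=ReactionRates(
                f_ca=m.rates.f_ca,
                f_nodes={_PAIR_KEYS[k]: tuple(v) for k, v in m.rates.f_nodes.items()},
            ),
            constants=MechanicsConstants(**m.constants.model_dump()),
            beat_period=m.beat_period,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def provenance(self) -> Dict[str, object]:
        return {
            "config_hash": self.config_hash(),
            "version": __version__,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
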