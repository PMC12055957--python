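"""Schema-validated YAML run configuration.

All lengths in the file are micrometres (the natural unit at chip scale);
they are converted to SI when building the solver configuration.  Unknown
keys are rejected.
"""

from __future__ import annotations

import pydantic
import yaml

from .params import DimensionlessGroups, FluidModel
from .transit_simulation import TransitConfig

__all__ = ["RunConfig", "load_config"]


class _Channel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    kind: str = "constricted"
    l_um: float = 20.0
    U: float = 0.19  # m/s
    nodes_per_l: int = 64
    straight_len_um: float = 400.0
    converging_len_um: float = 120.0
    feed_len_um: float = 440.0
    other_len_um: float = 160.0
    corner_r_um: float | None = None
    release_x_um: float | None = None


class _Fluid(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    K: float = 0.053  # Pa s
    alpha: float = 0.95
    gamma0: float = 1.0  # 1/s
    gamma_min: float = 0.01
    gamma_max: float = 1.0e6
    rho: float = 1060.0  # kg/m^3
    mu0: float = 32.7e-3  # Pa s


class _Cell(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    Ca: float = 0.6
    C: float = 10.0
    eta: float = 0.0
    lam: float = 1.0
    confinement: float = 0.74  # 2a/l
    an_over_a: float = 0.5
    d_oc_y: float = 0.0  # fractions of l
    d_oc_z: float = 0.0


class _Run(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    mesh_subdivisions: int = 5
    record_every: int = 100
    max_tstar: float = 25.0
    use_cache: bool = True


class RunConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    channel: _Channel = _Channel()
    fluid: _Fluid = _Fluid()
    cell: _Cell = _Cell()
    run: _Run = _Run()

    def fluid_model(self) -> FluidModel:
        return FluidModel(**self.fluid.model_dump())

    def groups(self) -> DimensionlessGroups:
        c = self.cell
        return DimensionlessGroups(Ca=c.Ca, C=c.C, eta=c.eta, lam=c.lam,
                                   confinement=c.confinement,
                                   an_over_a=c.an_over_a)

    def transit_config(self) -> TransitConfig:
        ch = self.channel
        return TransitConfig(
            kind=ch.kind,
            fluid=self.fluid_model(),
            groups=self.groups(),
            U=ch.U,
            l=ch.l_um * 1e-6,
            nodes_per_l=ch.nodes_per_l,
            mesh_subdivisions=self.run.mesh_subdivisions,
            d_oc_y=self.cell.d_oc_y,
            d_oc_z=self.cell.d_oc_z,
            release_x=(None if ch.release_x_um is None
                       else ch.release_x_um * 1e-6),
            straight_len=ch.straight_len_um * 1e-6,
            converging_len=ch.converging_len_um * 1e-6,
            feed_len=ch.feed_len_um * 1e-6,
            other_len=ch.other_len_um * 1e-6,
            corner_r=(None if ch.corner_r_um is None
                      else ch.corner_r_um * 1e-6),
            record_every=self.run.record_every,
            max_tstar=self.run.max_tstar,
            lam=self.cell.lam,
            use_cache=self.run.use_cache,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except pydantic.ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"invalid config key '{loc}': {first['msg']}") from err
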