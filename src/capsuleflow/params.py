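"""Fluid rheology, cell parameters, dimensionless groups and unit conversions.

All quantities are SI unless a name says otherwise.  The suspending medium
(PBS + 3 % methylcellulose) is weakly shear thinning and follows a truncated
power law

    mu(gamma_dot) = K * (gamma_dot / gamma0)**(alpha - 1),

clamped to ``[gamma_min, gamma_max]``.  The cell membrane follows the Skalak
law with shear modulus ``Gs`` and hardness parameter ``C`` so that the area
dilatation modulus is ``Ks = (1 + 2C) Gs``; its surface shear viscosity is
``mu_s``.  The dimensionless groups controlling a transit are

    Ca  = mu0 * U / Gs          (capillary number)
    eta = mu_s / (mu0 * a)      (dimensionless membrane viscosity)
    lam = mu_c / mu0            (cytoplasm / medium viscosity ratio)
    Re  = rho * U * l / mu0     (Reynolds number)

together with the confinement ratio ``2a/l`` and the nucleus size ratio
``a_n/a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidModel",
    "CellParams",
    "DimensionlessGroups",
    "ChannelSpec",
    "power_law_viscosity",
    "dimensionless_groups",
    "to_dimensional",
    "mean_duct_speed",
    "propagate_uncertainty",
    "cross_section_average_viscosity",
]


@dataclass(frozen=True)
class FluidModel:
    """Truncated power-law suspending medium.

    Parameters
    ----------
    K : float
        Consistency (Pa s at the reference shear rate).
    alpha : float
        Power-law index; 1 recovers a Newtonian fluid.
    gamma0 : float
        Reference shear rate (1/s) at which ``mu = K``.
    gamma_min, gamma_max : float
        Truncation bounds (1/s) for the local shear rate; wide defaults
        chosen so the clamp never bites at duct-flow shear rates of order
        ``U/l ~ 1e4 1/s``.
    rho : float
        Density (kg/m^3).
    mu0 : float
        Characteristic (cross-section-average) viscosity (Pa s) used in the
        dimensionless groups.
    """

    K: float = 0.053
    alpha: float = 0.95
    gamma0: float = 1.0
    gamma_min: float = 0.01
    gamma_max: float = 1.0e6
    rho: float = 1060.0
    mu0: float = 32.7e-3

    def __post_init__(self) -> None:
        if not (self.K > 0):
            raise ValueError("consistency K must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("power-law index alpha must lie in (0, 1]")
        if not (self.gamma_min < self.gamma_max):
            raise ValueError("gamma_min must be below gamma_max")
        if not (self.mu0 > 0 and self.rho > 0):
            raise ValueError("mu0 and rho must be positive")

    def viscosity(self, gamma_dot) -> np.ndarray | float:
        return power_law_viscosity(gamma_dot, self)

    @property
    def newtonian(self) -> bool:
        return self.alpha == 1.0


@dataclass(frozen=True)
class CellParams:
    """Compound-cell mechanical parameters.

    The nucleus is a smaller capsule, concentric at release, with membrane
    moduli ``Gsn_factor`` times those of the cell membrane (same hardness
    parameter), a purely hyperelastic membrane (no surface viscosity) and an
    interior at the cytoplasm viscosity.
    """

    a: float  # cell radius (m)
    Gs: float  # membrane shear modulus (N/m)
    C: float  # hardness parameter (-)
    mu_s: float = 0.0  # membrane shear viscosity (N s/m)
    mu_s_dil: float = 0.0  # membrane dilatational viscosity (N s/m)
    mu_c: float = 32.7e-3  # cytoplasm viscosity (Pa s)
    kc: float | None = None  # bending modulus (J); default 0.001*Gs*a^2
    c0: float = 0.0  # spontaneous curvature (1/m)
    an_over_a: float = 0.5  # nucleus size ratio
    Gsn_factor: float = 2.0  # nucleus membrane stiffness multiplier

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.Gs > 0):
            raise ValueError("cell radius and shear modulus must be positive")
        if self.C < 0 or self.mu_s < 0 or self.mu_s_dil < 0:
            raise ValueError("C, mu_s and mu_s_dil must be non-negative")
        if self.kc is None:
            object.__setattr__(self, "kc", 0.001 * self.Gs * self.a**2)
        if self.kc < 0:
            raise ValueError("bending modulus must be non-negative")

    @property
    def Ks(self) -> float:
        """Area-dilatation modulus, ``(1 + 2C) Gs`` (N/m)."""
        return (1.0 + 2.0 * self.C) * self.Gs

    # --- nucleus defaults -------------------------------------------------
    @property
    def a_n(self) -> float:
        return self.an_over_a * self.a

    @property
    def Gsn(self) -> float:
        return self.Gsn_factor * self.Gs

    @property
    def Ksn(self) -> float:
        return (1.0 + 2.0 * self.C) * self.Gsn

    @property
    def kcn(self) -> float:
        return 0.001 * self.Gsn * self.a_n**2


@dataclass(frozen=True)
class ChannelSpec:
    """Channel flow conditions: square cross-section of width ``l``.

    ``U`` is the mean speed in one branch of width ``l``; if a volumetric
    flow rate ``Q`` is given instead, ``U = Q / l**2``.
    """

    kind: str  # {"constricted", "cross_slot"}
    l: float  # channel width (m)
    U: float | None = None  # mean speed (m/s)
    Q: float | None = None  # volumetric flow rate per branch (m^3/s)

    def __post_init__(self) -> None:
        if self.kind not in ("constricted", "cross_slot"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if not (self.l > 0):
            raise ValueError("channel width must be positive")
        if self.U is None and self.Q is None:
            raise ValueError("one of U or Q is required")
        if self.U is None:
            object.__setattr__(self, "U", mean_duct_speed(self.Q, self.l))
        elif self.Q is None:
            object.__setattr__(self, "Q", self.U * self.l**2)


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless groups of a transit."""

    Ca: float
    C: float
    eta: float = 0.0
    lam: float = 1.0
    confinement: float = 0.0  # 2a/l
    an_over_a: float = 0.5
    Re: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Ca", "C", "eta", "lam", "confinement", "an_over_a", "Re"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def power_law_viscosity(gamma_dot, fluid: FluidModel):
    """Truncated power-law viscosity ``K (gamma/gamma0)**(alpha-1)`` (Pa s).

    The shear rate is clamped to ``[gamma_min, gamma_max]`` before
    evaluation, so the viscosity stays bounded as ``gamma_dot -> 0``.
    Accepts scalars or arrays.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    g = np.clip(g, fluid.gamma_min, fluid.gamma_max)
    mu = fluid.K * (g / fluid.gamma0) ** (fluid.alpha - 1.0)
    return float(mu) if np.isscalar(gamma_dot) or np.ndim(gamma_dot) == 0 else mu


def mean_duct_speed(Q: float, l: float) -> float:
    """Mean speed ``U = Q / l**2`` of a square duct of width ``l``."""
    if not (l > 0):
        raise ValueError("duct width must be positive")
    return Q / l**2


def dimensionless_groups(
    fluid: FluidModel, cell: CellParams, chan: ChannelSpec
) -> DimensionlessGroups:
    """Form the dimensionless groups from dimensional parameters."""
    if fluid.mu0 <= 0 or cell.Gs <= 0:
        raise ValueError("mu0 and Gs must be positive")
    U = chan.U
    return DimensionlessGroups(
        Ca=fluid.mu0 * U / cell.Gs,
        C=cell.C,
        eta=cell.mu_s / (fluid.mu0 * cell.a),
        lam=cell.mu_c / fluid.mu0,
        confinement=2.0 * cell.a / chan.l,
        an_over_a=cell.an_over_a,
        Re=fluid.rho * U * chan.l / fluid.mu0,
    )


def to_dimensional(
    groups: DimensionlessGroups, fluid: FluidModel, U: float, a: float
) -> tuple[float, float, float]:
    """Invert the groups into dimensional moduli ``(Gs, Ks, mu_s)``.

    ``Gs = mu0 U / Ca`` (N/m), ``Ks = (1 + 2C) Gs`` (N/m),
    ``mu_s = eta mu0 a`` (N s/m).
    """
    if groups.Ca <= 0:
        raise ValueError("Ca must be positive to invert")
    Gs = fluid.mu0 * U / groups.Ca
    Ks = (1.0 + 2.0 * groups.C) * Gs
    mu_s = groups.eta * fluid.mu0 * a
    return Gs, Ks, mu_s


def propagate_uncertainty(
    best: tuple[float, float, float],
    increments: tuple[float, float, float],
    fluid: FluidModel,
    U: float,
    a: float,
) -> tuple[float, float, float]:
    """Half-increment uncertainties of the dimensional moduli.

    The inverse fit scans ``(Ca, C, eta)`` on a finite grid; a best-fit value
    is therefore known only to half a grid increment.  With
    ``dCa = delta_Ca / 2`` etc.,

        dGs   = Gs * dCa / Ca
        dmu_s = mu_s * deta / eta          (one half-increment bound if eta = 0)
        dKs   = sqrt((2 Gs dC)^2 + ((1 + 2C) dGs)^2)   (quadrature)

    Returns ``(dGs, dKs, dmu_s)`` in (N/m, N/m, N s/m).
    """
    Ca, C, eta = best
    dCa, dC, deta = (x / 2.0 for x in increments)
    if Ca <= 0:
        raise ValueError("best-fit Ca must be positive")
    Gs = fluid.mu0 * U / Ca
    mu_s = eta * fluid.mu0 * a
    dGs = Gs * dCa / Ca
    dKs = math.hypot(2.0 * Gs * dC, (1.0 + 2.0 * C) * dGs)
    if eta > 0:
        dmu_s = mu_s * deta / eta
    else:
        # one-sided bound: eta known only to be below half an increment
        dmu_s = deta * fluid.mu0 * a
    return dGs, dKs, dmu_s


def cross_section_average_viscosity(
    fluid: FluidModel, U: float, l: float, n: int = 64, flow_weighted: bool = False
) -> float:
    """Area-average (or flow-weighted) viscosity over a square duct section.

    Auxiliary diagnostic: evaluates the power-law viscosity on the analytic
    Newtonian square-duct velocity profile scaled to mean speed ``U`` and
    averages it over the cross-section.  ``mu0`` itself is an input taken
    from measurement, not recomputed from this.
    """
    from .fixtures import square_duct_newtonian

    y = (np.arange(n) + 0.5) / n * l - l / 2
    z = y.copy()
    Y, Z = np.meshgrid(y, z, indexing="ij")
    u = square_duct_newtonian(Y, Z, l, U=U)
    du_dy, du_dz = np.gradient(u, y, z)
    gd = np.sqrt(du_dy**2 + du_dz**2)
    mu = power_law_viscosity(gd, fluid)
    if flow_weighted:
        return float(np.sum(mu * u) / np.sum(u))
    return float(np.mean(mu))
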