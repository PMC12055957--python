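"""Closed-form reference flows used as solver oracles.

These analytic fields validate the lattice-Boltzmann solver against known
solutions: plane Poiseuille flow (Newtonian and power-law), the classic
Fourier-series solution for a square duct, and linear Couette shear.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plane_poiseuille_newtonian",
    "plane_poiseuille_powerlaw",
    "square_duct_newtonian",
    "square_duct_flow_coefficient",
    "linear_shear",
    "analytic_flow_fixtures",
]


def plane_poiseuille_newtonian(y, h: float, G: float, mu: float):
    """u(y) = G/(2 mu) (h^2 - y^2) between plates at y = +-h, pressure
    gradient (force density) G."""
    y = np.asarray(y, dtype=float)
    return G / (2.0 * mu) * (h**2 - y**2)


def plane_poiseuille_powerlaw(y, h: float, G: float, K: float, alpha: float,
                              gamma0: float = 1.0):
    """Power-law plane Poiseuille profile.

    With mu = K (gd/gamma0)**(alpha-1), i.e. shear stress m gd**alpha with
    m = K gamma0**(1-alpha):

        u(y) = alpha/(alpha+1) (G/m)**(1/alpha) (h**(1+1/alpha) - |y|**(1+1/alpha))
    """
    y = np.asarray(y, dtype=float)
    m = K * gamma0 ** (1.0 - alpha)
    n = 1.0 / alpha
    return (G / m) ** n / (n + 1.0) * (h ** (n + 1.0) - np.abs(y) ** (n + 1.0))


def square_duct_newtonian(y, z, l: float, G: float | None = None,
                          mu: float = 1.0, U: float | None = None,
                          nterms: int = 101):
    """Fourier-series velocity of a square duct of width ``l`` (walls at
    y, z = +-l/2).  Give either the pressure gradient ``G`` (with ``mu``) or
    the mean speed ``U`` to scale the profile.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a = l / 2.0
    u = np.zeros(np.broadcast(y, z).shape)
    for k in range(nterms):
        n = 2 * k + 1
        beta = n * np.pi / (2.0 * a)
        term = (
            ((-1.0) ** k / n**3)
            * (1.0 - np.cosh(beta * z) / np.cosh(beta * a))
            * np.cos(beta * y)
        )
        u = u + term
    u *= 16.0 * a**2 / np.pi**3  # profile for G/mu = 1
    if U is not None:
        mean_u = square_duct_flow_coefficient(nterms) * a**2
        return u * (U / mean_u)
    if G is None:
        raise ValueError("give G or U")
    return u * (G / mu)


def square_duct_flow_coefficient(nterms: int = 101) -> float:
    """Mean-speed coefficient of a square duct, U_mean = c a^2 (G/mu).

    ``a = l/2`` is the half-width.  Textbook series:

        c = (1/3) [1 - (192/pi^5) sum_{n odd} tanh(n pi / 2) / n^5]

    which evaluates to c = 0.14058 (equivalently Q = 0.5623 G a^4 / mu).
    """
    s = 0.0
    for k in range(nterms):
        n = 2 * k + 1
        s += np.tanh(n * np.pi / 2.0) / n**5
    return (1.0 - 192.0 / np.pi**5 * s) / 3.0


def linear_shear(z, gamma_dot: float):
    """Couette field u_x = gamma_dot * z."""
    return gamma_dot * np.asarray(z, dtype=float)


def analytic_flow_fixtures(case: str, **kw):
    """Dispatch by case name; returns a dict of reference fields.

    Cases: plane_poiseuille_newtonian, plane_poiseuille_powerlaw,
    square_duct_newtonian, linear_shear.
    """
    if case == "plane_poiseuille_newtonian":
        y = np.asarray(kw["y"])
        u = plane_poiseuille_newtonian(y, kw["h"], kw["G"], kw["mu"])
        return {"u": u, "gamma_dot": np.abs(kw["G"] * y / kw["mu"])}
    if case == "plane_poiseuille_powerlaw":
        y = np.asarray(kw["y"])
        u = plane_poiseuille_powerlaw(
            y, kw["h"], kw["G"], kw["K"], kw["alpha"], kw.get("gamma0", 1.0)
        )
        m = kw["K"] * kw.get("gamma0", 1.0) ** (1.0 - kw["alpha"])
        gd = (kw["G"] * np.abs(y) / m) ** (1.0 / kw["alpha"])
        return {"u": u, "gamma_dot": gd}
    if case == "square_duct_newtonian":
        u = square_duct_newtonian(
            kw["y"], kw["z"], kw["l"], kw.get("G"), kw.get("mu", 1.0),
            kw.get("U"),
        )
        return {"u": u}
    if case == "linear_shear":
        z = np.asarray(kw["z"])
        return {
            "u": linear_shear(z, kw["gamma_dot"]),
            "gamma_dot": np.full(z.shape, float(kw["gamma_dot"])),
        }
    raise ValueError(f"unknown fixture case {case!r}")
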