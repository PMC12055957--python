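"""Inverse inference of cell-membrane mechanics from observed contours.

The procedure has up to three stages, mirroring how the forward model is
used against deformability-cytometry recordings:

1. *Steady shape* — the membrane elastic moduli.  Hyperelastic forward
   simulations are scanned over (Ca, C); candidates that reproduce the
   observed steady deformation index within a tolerance are ranked by the
   directed mean Hausdorff distance (MHD) between steady contours, and the
   minimum-MHD candidate wins.
2. *Transient deformation* — the membrane viscosity.  With (Ca, C) fixed,
   simulations over the dimensionless membrane viscosity eta are compared
   with the observed DI (constricted) or D_XZ (cross-slot) series; the
   RMS-minimising eta wins.
3. *Trajectory* — the initial off-centre distance in the cross-slot, fitted
   on the z(t*) trajectory with a hyperelastic (eta = 0) library, because
   the residence time is insensitive to membrane viscosity.

Because each stage scans a finite grid, a best-fit value is known to half a
grid increment; uncertainties of the dimensional moduli follow by
propagation.  The scan is exposed statsmodels-style: a model object built
from the observations whose ``fit()`` returns a results object with the
estimates, their uncertainties and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .params import FluidModel, propagate_uncertainty, to_dimensional, \
    DimensionlessGroups
from .shape_metrics import ContourProfile, mean_hausdorff

__all__ = [
    "FitGrid",
    "FitResult",
    "fit_steady",
    "fit_membrane_viscosity",
    "fit_offcenter",
    "report",
    "CellMechanicsModel",
    "CellMechanicsResults",
]


@dataclass(frozen=True)
class FitGrid:
    """Scan grid of the parameter inference.

    Defaults reproduce the full study scan: 0.1 <= Ca <= 5 (step 0.1),
    1 <= C <= 50 (step 1), 0 <= eta <= 80 (step 5), and off-centre
    distances 0.001 l ... 0.016 l.
    """

    Ca: np.ndarray = dfield(
        default_factory=lambda: np.round(np.arange(0.1, 5.0001, 0.1), 10))
    C: np.ndarray = dfield(
        default_factory=lambda: np.arange(1.0, 50.001, 1.0))
    eta: np.ndarray = dfield(
        default_factory=lambda: np.arange(0.0, 80.001, 5.0))
    d_oc: np.ndarray = dfield(
        default_factory=lambda: np.array(
            [0.001, 0.002, 0.004, 0.007, 0.01, 0.013, 0.016]))

    def __post_init__(self) -> None:
        for name in ("Ca", "C", "eta", "d_oc"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if len(v) > 1 and np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")

    @property
    def dCa(self) -> float:
        return float(np.diff(self.Ca).min()) if len(self.Ca) > 1 else 0.1

    @property
    def dC(self) -> float:
        return float(np.diff(self.C).min()) if len(self.C) > 1 else 1.0

    @property
    def deta(self) -> float:
        return float(np.diff(self.eta).min()) if len(self.eta) > 1 else 5.0


@dataclass
class FitResult:
    """Best-fit dimensionless parameters and their dimensional conversion."""

    Ca: float
    C: float
    eta: float = 0.0
    d_oc: float | None = None
    mhd: float = np.nan  # um, at the steady-shape optimum
    Gs: float = np.nan  # N/m
    Ks: float = np.nan
    mu_s: float = np.nan  # N s/m
    dGs: float = np.nan
    dKs: float = np.nan
    dmu_s: float = np.nan
    tables: dict = dfield(default_factory=dict)
    flags: list = dfield(default_factory=list)


def fit_steady(
    exp_contour,
    exp_DI: float,
    library: dict,
    tol_DI: float = 0.005,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Stage 1: select (Ca, C) from steady contours.

    ``library`` maps (Ca, C) -> (steady_DI, steady_contour); contours are
    (k, 2) x-z polylines in um.  Candidates within ``tol_DI`` of the
    observed steady DI are ranked by MHD (simulation -> experiment); ties
    break toward the lowest Ca, then the lowest C.
    """
    rows = []
    for (Ca, C), (di, contour) in sorted(library.items()):
        mhd = mean_hausdorff(contour, exp_contour)
        rows.append({"Ca": Ca, "C": C, "DI": di, "MHD": mhd,
                     "shortlisted": abs(di - exp_DI) <= tol_DI})
    table = pd.DataFrame(rows)
    pool = table[table.shortlisted]
    if len(pool) == 0:
        pool = table
        table.attrs["warning"] = "empty shortlist; global MHD minimum used"
    pool = pool.sort_values(["MHD", "Ca", "C"], kind="stable")
    best = pool.iloc[0]
    return (float(best.Ca), float(best.C)), table


def _series_rms(x_obs, y_obs, x_sim, y_sim) -> float:
    """RMS difference on the overlap of two sampled curves."""
    lo = max(np.min(x_obs), np.min(x_sim))
    hi = min(np.max(x_obs), np.max(x_sim))
    span_obs = np.max(x_obs) - np.min(x_obs)
    if hi - lo < 0.5 * span_obs:
        raise ValueError("simulated and observed series overlap by < 50%")
    xs = np.linspace(lo, hi, 200)
    yo = np.interp(xs, x_obs, y_obs)
    ys = np.interp(xs, x_sim, y_sim)
    return float(np.sqrt(np.mean((yo - ys) ** 2)))


def fit_membrane_viscosity(
    exp_series: tuple[np.ndarray, np.ndarray],
    library: dict,
) -> tuple[float, pd.DataFrame]:
    """Stage 2: select eta from the transient deformation series.

    ``exp_series`` is (abscissa, deformation) — DI versus centroid position
    in the constricted channel, or D_XZ versus t* in the cross-slot.
    ``library`` maps eta -> (abscissa, deformation).  Returns the
    RMS-minimising eta and the full discrepancy table; entries whose RMS
    exceeds twice the minimum are flagged (e.g. an eta = 0 library against
    a viscoelastic observation).
    """
    x_obs, y_obs = (np.asarray(v, dtype=float) for v in exp_series)
    rows = []
    for eta, (x_sim, y_sim) in sorted(library.items()):
        rows.append({"eta": eta,
                     "rms": _series_rms(x_obs, y_obs, x_sim, y_sim)})
    table = pd.DataFrame(rows)
    table["underdamped"] = table.rms > 2.0 * table.rms.min()
    best = table.sort_values(["rms", "eta"], kind="stable").iloc[0]
    return float(best.eta), table


def fit_offcenter(
    exp_traj: tuple[np.ndarray, np.ndarray],
    library: dict,
    l: float,
) -> tuple[float, pd.DataFrame]:
    """Stage 3: infer the initial off-centre distance d_oc^z.

    ``exp_traj`` is (t*, z) with t* = 0 at cross-slot entry; ``library``
    maps d_oc (fraction of l, positive) -> (t*, z) from hyperelastic
    simulations.  A trajectory exiting downward is matched against the
    mirrored library and returns a negative d_oc.
    """
    tstar, z = (np.asarray(v, dtype=float) for v in exp_traj)
    if np.max(np.abs(z)) < 0.5 * l:
        raise ValueError("observed cell never exits the cross-slot region")
    sign = 1.0 if z[np.argmax(np.abs(z))] > 0 else -1.0
    rows = []
    for d, (ts, zs) in sorted(library.items()):
        rows.append({"d_oc": d,
                     "rms": _series_rms(tstar, sign * z, ts, zs)})
    table = pd.DataFrame(rows)
    best = table.sort_values(["rms", "d_oc"], kind="stable").iloc[0]
    return sign * float(best.d_oc), table


def report(fit: FitResult, fluid: FluidModel, U: float, a: float,
           grid: FitGrid | None = None) -> FitResult:
    """Fill in dimensional moduli and half-increment uncertainties."""
    grid = grid or FitGrid()
    groups = DimensionlessGroups(Ca=fit.Ca, C=fit.C, eta=fit.eta)
    fit.Gs, fit.Ks, fit.mu_s = to_dimensional(groups, fluid, U, a)
    fit.dGs, fit.dKs, fit.dmu_s = propagate_uncertainty(
        (fit.Ca, fit.C, fit.eta), (grid.dCa, grid.dC, grid.deta),
        fluid, U, a)
    return fit


class CellMechanicsModel:
    """Inverse model of one observed cell transit.

    Parameters
    ----------
    exp_contour : (k, 2) array or ContourProfile
        Observed steady x-z contour (um).
    exp_DI : float
        Observed steady deformation index.
    steady_library : dict
        (Ca, C) -> (steady_DI, contour) forward library.
    transient_series, transient_library : optional
        Observed deformation series and eta -> series library (stage 2).
    trajectory, trajectory_library : optional
        Observed (t*, z) trajectory and d_oc -> (t*, z) library (stage 3).
    fluid, U, a :
        Flow conditions used to dimensionalise the result.
    """

    def __init__(self, exp_contour, exp_DI, steady_library,
                 fluid: FluidModel, U: float, a: float,
                 transient_series=None, transient_library=None,
                 trajectory=None, trajectory_library=None,
                 l: float | None = None,
                 grid: FitGrid | None = None, tol_DI: float = 0.005):
        self.exp_contour = (exp_contour.points
                            if isinstance(exp_contour, ContourProfile)
                            else np.asarray(exp_contour, dtype=float))
        self.exp_DI = float(exp_DI)
        self.steady_library = steady_library
        self.transient_series = transient_series
        self.transient_library = transient_library
        self.trajectory = trajectory
        self.trajectory_library = trajectory_library
        self.fluid = fluid
        self.U = U
        self.a = a
        self.l = l
        self.grid = grid or FitGrid()
        self.tol_DI = tol_DI

    def fit(self) -> "CellMechanicsResults":
        fitres = FitResult(Ca=np.nan, C=np.nan)
        (Ca, C), table1 = fit_steady(self.exp_contour, self.exp_DI,
                                     self.steady_library, self.tol_DI)
        fitres.Ca, fitres.C = Ca, C
        fitres.tables["steady"] = table1
        sel = table1[(table1.Ca == Ca) & (table1.C == C)]
        fitres.mhd = float(sel.MHD.iloc[0])
        if "warning" in table1.attrs:
            fitres.flags.append(table1.attrs["warning"])
        if self.transient_series is not None and self.transient_library:
            eta, table2 = fit_membrane_viscosity(self.transient_series,
                                                 self.transient_library)
            fitres.eta = eta
            fitres.tables["transient"] = table2
        if self.trajectory is not None and self.trajectory_library:
            if self.l is None:
                raise ValueError("channel width l required for stage 3")
            d, table3 = fit_offcenter(self.trajectory,
                                      self.trajectory_library, self.l)
            fitres.d_oc = d
            fitres.tables["trajectory"] = table3
        report(fitres, self.fluid, self.U, self.a, self.grid)
        return CellMechanicsResults(self, fitres)


class CellMechanicsResults:
    """Results of a :class:`CellMechanicsModel` fit."""

    def __init__(self, model: CellMechanicsModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> dict:
        f = self._fit
        return {"Ca": f.Ca, "C": f.C, "eta": f.eta, "d_oc": f.d_oc}

    @property
    def dimensional(self) -> dict:
        f = self._fit
        return {"Gs": f.Gs, "Ks": f.Ks, "mu_s": f.mu_s}

    @property
    def uncertainties(self) -> dict:
        f = self._fit
        return {"Gs": f.dGs, "Ks": f.dKs, "mu_s": f.dmu_s}

    @property
    def tables(self) -> dict:
        return self._fit.tables

    @property
    def mhd(self) -> float:
        return self._fit.mhd

    @property
    def flags(self) -> list:
        return self._fit.flags

    def to_dict(self) -> dict:
        f = self._fit
        return {
            "Ca": f.Ca, "C": f.C, "eta": f.eta, "d_oc": f.d_oc,
            "MHD_um": f.mhd,
            "Gs_mN_per_m": f.Gs * 1e3, "dGs_mN_per_m": f.dGs * 1e3,
            "Ks_mN_per_m": f.Ks * 1e3, "dKs_mN_per_m": f.dKs * 1e3,
            "mu_s_uN_s_per_m": f.mu_s * 1e6,
            "dmu_s_uN_s_per_m": f.dmu_s * 1e6,
        }

    def summary(self) -> str:
        """Human-readable table of the inferred membrane properties."""
        f = self._fit
        lines = [
            "Inferred cell membrane mechanical properties",
            "=" * 46,
            f"{'cell radius a':<28}{self.model.a * 1e6:8.1f}  um",
            f"{'capillary number Ca':<28}{f.Ca:8.2f}",
            f"{'hardness parameter C':<28}{f.C:8.1f}",
            f"{'membrane viscosity eta':<28}{f.eta:8.1f}",
        ]
        if f.d_oc is not None:
            lines.append(f"{'off-centre distance d/l':<28}{f.d_oc:8.4f}")
        lines += [
            "-" * 46,
            f"{'G_s (mN/m)':<20}{f.Gs * 1e3:8.1f} +/- {f.dGs * 1e3:.1f}",
            f"{'K_s (mN/m)':<20}{f.Ks * 1e3:8.1f} +/- {f.dKs * 1e3:.1f}",
            f"{'mu_s (uN s/m)':<20}{f.mu_s * 1e6:8.1f} +/- {f.dmu_s * 1e6:.1f}",
            "=" * 46,
        ]
        if not np.isnan(f.mhd):
            lines.insert(5, f"{'MHD at optimum':<28}{f.mhd:8.2f}  um")
        if f.flags:
            lines += [f"note: {fl}" for fl in f.flags]
        return "\n".join(lines)
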