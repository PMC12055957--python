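"""Canonical study conditions and their reduced-scale counterparts.

The full-scale conditions reproduce the experiments: a constricted channel
(l = 20 um, U = 0.19 m/s, mu0 = 32.7 mPa s) with a PC-3-like cell at
2a/l = 0.74, and a cross-slot channel (l = 40 um, U = 0.17 m/s,
mu0 = 33.9 mPa s) with a cell at 2a/l = 0.43; production lattice
resolution is l/64 with an 8192-element membrane mesh.

The reduced-scale presets keep every physical parameter identical and
shrink only the numerical problem: lattice l/12-l/16, a 512-element
membrane, and shortened converging/feed/outlet sections (the study's own
domain-shortening check found the deformation insensitive to upstream
truncation).  These are the conditions exercised by the test suite and the
acceptance script on desk-scale hardware.
"""

from __future__ import annotations

from .params import DimensionlessGroups, FluidModel
from .transit_simulation import TransitConfig

__all__ = [
    "constricted_fluid",
    "cross_slot_fluid",
    "constricted_reduced",
    "cross_slot_reduced",
    "feed_duct_reduced",
]


def constricted_fluid() -> FluidModel:
    """Suspending medium of the constricted-channel experiments."""
    return FluidModel(mu0=32.7e-3)


def cross_slot_fluid() -> FluidModel:
    """Suspending medium of the cross-slot experiments."""
    return FluidModel(mu0=33.9e-3)


def constricted_reduced(eta: float = 0.0, Ca: float = 0.6, C: float = 10.0,
                        confinement: float = 0.74,
                        use_cache: bool = True) -> TransitConfig:
    """PC-3-like constricted transit at reduced scale (lattice l/12)."""
    return TransitConfig(
        kind="constricted",
        fluid=constricted_fluid(),
        groups=DimensionlessGroups(Ca=Ca, C=C, eta=eta, lam=1.0,
                                   confinement=confinement, an_over_a=0.5),
        U=0.19, l=20e-6, nodes_per_l=12,
        converging_len=60e-6, straight_len=70e-6, release_x=-36e-6,
        record_every=50, max_tstar=25.0, use_cache=use_cache,
    )


def cross_slot_reduced(eta: float = 0.0, d_oc_z: float = 0.007,
                       Ca: float = 1.0, C: float = 10.0,
                       confinement: float = 0.43,
                       use_cache: bool = True) -> TransitConfig:
    """Cross-slot transit at reduced scale (lattice l/16, short branches)."""
    return TransitConfig(
        kind="cross_slot",
        fluid=cross_slot_fluid(),
        groups=DimensionlessGroups(Ca=Ca, C=C, eta=eta, lam=1.0,
                                   confinement=confinement, an_over_a=0.5),
        U=0.17, l=40e-6, nodes_per_l=16,
        feed_len=100e-6, other_len=80e-6, d_oc_z=d_oc_z,
        record_every=40, max_tstar=12.0, use_cache=use_cache,
    )


def feed_duct_reduced(Ca: float = 1.0, C: float = 10.0, eta: float = 0.0,
                      confinement: float = 0.43,
                      use_cache: bool = True) -> TransitConfig:
    """Straight feed duct of the cross-slot chip (steady-shape libraries)."""
    return TransitConfig(
        kind="straight",
        fluid=cross_slot_fluid(),
        groups=DimensionlessGroups(Ca=Ca, C=C, eta=eta, lam=1.0,
                                   confinement=confinement, an_over_a=0.5),
        U=0.17, l=40e-6, nodes_per_l=16, straight_len=200e-6,
        record_every=40, max_tstar=12.0, use_cache=use_cache,
    )
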