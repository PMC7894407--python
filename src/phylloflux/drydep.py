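"""Resistance-in-series dry deposition.

The deposition velocity of a gas to vegetation is the inverse of three
resistances in series — aerodynamic (ra), quasi-laminar boundary layer
(rb) and bulk surface (rc) — with rc the parallel combination of four
pathways::

    1/rc = 1/(rs + rm) + 1/rlu + 1/(rdc + rcl) + 1/(rac + rgs)
    vd   = 1 / (ra + rb + rc)

Species dependence enters through the effective Henry constant H*
(M atm^-1) and the surface reactivity factor f0 in [0, 1]:

    rs  = rs_base * sqrt(M / M_H2O)          (diffusivity scaling)
    rm  = 1 / (H*/3000 + 100 * f0)
    rlu = rlu_base / (1e-5 * H* + f0)
    rcl = 1 / (1e-5 * H* / rcl_s + f0 / rcl_o)
    rgs = 1 / (1e-5 * H* / rgs_s + f0 / rgs_o)

where the `_s`/`_o` base resistances are tabulated for SO2 and O3.  The
detailed land-use tables of the full scheme are reduced to per-call base
resistances supplied via :class:`SurfaceEnvironment`.

For 1,2-ISOPOOH and MVK over land the package also provides the
laboratory-constrained constant day/night velocities; over ocean the
resistance scheme itself is the delegation target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .species import REGISTRY, SpeciesProperties, SpeciesRegistry

_M_H2O = 18.015

#: Sentinel returned when a prescribed velocity does not apply and the
#: caller must fall back to the resistance scheme.
USE_RESISTANCE_SCHEME = "use_resistance_scheme"

#: Laboratory-constrained constant velocities over land, cm s^-1,
#: keyed by (species, is_day).
PRESCRIBED_LAND_VD = {
    ("isopooh_12", True): 0.79,
    ("isopooh_12", False): 0.12,
    ("mvk", True): 0.22,
    ("mvk", False): 0.044,
}


@dataclass(frozen=True)
class SurfaceEnvironment:
    """Base (reference-gas) resistances for one surface type, s m^-1."""

    rs_base: float = 100.0    # stomatal, water vapour
    rlu_base: float = 2000.0  # upper-canopy cuticle, reference scale
    rcl_s: float = 2000.0     # lower canopy, SO2
    rcl_o: float = 1000.0     # lower canopy, O3
    rgs_s: float = 500.0      # ground, SO2
    rgs_o: float = 200.0      # ground, O3
    rac: float = 2000.0       # in-canopy aerodynamic
    rdc: float = 100.0        # gas-phase convective (lower canopy)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ResistanceSet:
    """Component resistances, s m^-1; ``None`` marks an open circuit."""

    ra: float | None = None
    rb: float | None = None
    rs: float | None = None
    rm: float | None = None
    rlu: float | None = None
    rdc: float | None = None
    rcl: float | None = None
    rac: float | None = None
    rgs: float | None = None

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DepositionResult:
    vd: float                  # cm s^-1
    rc: float                  # s m^-1 (inf when no branch conducts)
    stomatal_fraction: float   # in [0, 1]
    no_surface_pathway: bool = False


def _series(*components: float | None) -> float | None:
    """Series combination; any absent component opens the branch."""
    if any(c is None for c in components):
        return None
    return float(sum(components))  # type: ignore[arg-type]


def surface_resistance(species: SpeciesProperties | str,
                       env: SurfaceEnvironment = SurfaceEnvironment(),
                       registry: SpeciesRegistry = REGISTRY) -> ResistanceSet:
    """Scale the surface pathway resistances to a species' H* and f0."""
    sp = registry[species] if isinstance(species, str) else species
    hstar, f0 = sp.henry_eff, sp.f0
    if hstar <= 0:
        raise ValueError("H* must be > 0")

    rs = env.rs_base * math.sqrt(sp.molar_mass / _M_H2O)
    rm = 1.0 / (hstar / 3000.0 + 100.0 * f0)
    sol = 1e-5 * hstar
    rlu = env.rlu_base / (sol + f0) if (sol + f0) > 0 else None
    rcl_c = sol / env.rcl_s if env.rcl_s > 0 else 0.0
    rcl_c += f0 / env.rcl_o if env.rcl_o > 0 else 0.0
    rgs_c = sol / env.rgs_s if env.rgs_s > 0 else 0.0
    rgs_c += f0 / env.rgs_o if env.rgs_o > 0 else 0.0
    return ResistanceSet(
        rs=rs, rm=rm,
        rlu=rlu,
        rcl=(1.0 / rcl_c) if rcl_c > 0 else None,
        rgs=(1.0 / rgs_c) if rgs_c > 0 else None,
        rac=env.rac, rdc=env.rdc)


def total_vd(ra: float, rb: float, rc_set: ResistanceSet) -> DepositionResult:
    """Combine the resistance network into a deposition velocity.

    Absent branches are open circuits.  When no surface branch conducts
    the result carries vd = 0 with ``no_surface_pathway`` set rather
    than raising.
    """
    if ra < 0 or rb < 0:
        raise ValueError("ra and rb must be >= 0")
    branches = {
        "stomatal": _series(rc_set.rs, rc_set.rm),
        "cuticle": rc_set.rlu,
        "lower_canopy": _series(rc_set.rdc, rc_set.rcl),
        "ground": _series(rc_set.rac, rc_set.rgs),
    }
    conductances = {k: (1.0 / r if r is not None and r > 0 else
                        (math.inf if r == 0 else 0.0))
                    for k, r in branches.items()}
    g_total = sum(conductances.values())
    if g_total == 0:
        return DepositionResult(0.0, math.inf, 0.0, no_surface_pathway=True)
    rc = 1.0 / g_total
    vd_ms = 1.0 / (ra + rb + rc)
    frac = conductances["stomatal"] / g_total if math.isfinite(g_total) else (
        1.0 if math.isinf(conductances["stomatal"]) else 0.0)
    return DepositionResult(vd_ms * 100.0, rc, frac)


def prescribed_vd(species: SpeciesProperties | str, is_day: bool, is_land: bool,
                  registry: SpeciesRegistry = REGISTRY) -> float | str:
    """Constant land deposition velocity (cm s^-1) for 1,2-ISOPOOH or
    MVK, or the :data:`USE_RESISTANCE_SCHEME` marker over ocean."""
    sp = registry[species] if isinstance(species, str) else species
    if sp.name not in {"isopooh_12", "mvk"}:
        raise KeyError(f"no prescribed deposition velocity for {sp.name!r}")
    if not is_land:
        return USE_RESISTANCE_SCHEME
    return PRESCRIBED_LAND_VD[(sp.name, bool(is_day))]


def daynight_average(vd_day: float, vd_night: float, day_fraction: float) -> float:
    """Time-weighted 24-h mean velocity."""
    if not 0.0 <= day_fraction <= 1.0:
        raise ValueError("day_fraction must lie in [0, 1]")
    return day_fraction * vd_day + (1.0 - day_fraction) * vd_night


def is_daytime(solar_zenith_deg: float) -> bool:
    """Binary day/night classification helper (sun above the horizon)."""
    return solar_zenith_deg < 90.0
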