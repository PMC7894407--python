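"""Enclosure (cuvette) exchange estimation.

A plant sealed in a well-mixed, flushed enclosure removes (or releases)
trace gases; the deposition flux follows from the outlet deficit relative
to the empty, surface-conditioned enclosure:

    Phi_i = (F_out,BG - F_out,plant) / LA        [deposition => Phi < 0]

with F the molar flow of species *i* at the outlet (vmr * 1e-9 * p*Q/(R*T))
and LA the single-sided leaf area.  The deposition velocity is

    v_d,i = -Phi_i / c_i

with c_i the gas concentration the leaf is exposed to (the well-mixed
enclosure's outlet concentration during the plant phase), so net
deposition gives v_d > 0.  In-leaf conversion yields are molar flux
ratios: (product emission) / (parent deposition), per light condition.

Series are tidy :class:`pandas.DataFrame` objects with one row per sample
and columns::

    time_s, phase {inlet|background|plant}, light {dark|light},
    flow_lpm, leaf_area_m2, temperature_K, pressure_Pa, vmr_<species>...

Replicated experiments are lists of such frames; uncertainties are the
standard deviation across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import R_GAS, lpm_to_m3s
from .species import REGISTRY, SpeciesProperties, SpeciesRegistry

SERIES_META_COLUMNS = ("time_s", "phase", "light", "flow_lpm", "leaf_area_m2",
                      "temperature_K", "pressure_Pa")


class MissingPhaseError(ValueError):
    """A required enclosure phase is absent from the series."""


@dataclass(frozen=True)
class Concentration:
    """A gas concentration with molar and mass views.

    ``ug_cm3`` is numerically equal to ``mol_m3 * molar_mass`` because
    1 g m^-3 == 1 ug cm^-3.
    """

    mol_m3: float
    molar_mass: float | None = None

    @property
    def ug_cm3(self) -> float:
        if self.molar_mass is None:
            raise ValueError("mass view requires species molar mass")
        return self.mol_m3 * self.molar_mass


@dataclass(frozen=True)
class FluxEstimate:
    """Leaf-area-normalised exchange flux (negative = deposition)."""

    species: str
    condition: str            # "dark" | "light"
    flux: float               # nmol m^-2 s^-1
    uncertainty: float        # same units, std across replicates
    n: int                    # replicate count

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class DepositionVelocity:
    species: str
    vd: float                 # cm s^-1, positive for deposition
    condition: str
    uncertainty: float = 0.0


@dataclass(frozen=True)
class YieldEstimate:
    parent: str
    product: str
    condition: str
    value: float              # molar fraction of deposited parent re-emitted
    uncertainty: float
    n: int
    exceeds_unity: bool = False


def vmr_to_concentration(vmr_ppbv: float, temperature: float, pressure: float,
                         species: SpeciesProperties | None = None) -> Concentration:
    """Ideal-gas conversion of a volume mixing ratio to concentration.

    c = vmr * 1e-9 * p / (R*T)  in mol m^-3; the mass view (ug cm^-3)
    follows from the species molar mass.  Inverse of
    :func:`concentration_to_vmr`.
    """
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be > 0")
    vmr = np.asarray(vmr_ppbv, dtype=float)
    if np.any(vmr < 0):
        raise ValueError("vmr must be >= 0")
    c = float(vmr) * 1e-9 * pressure / (R_GAS * temperature)
    return Concentration(c, None if species is None else species.molar_mass)


def concentration_to_vmr(mol_m3: float, temperature: float, pressure: float) -> float:
    """Inverse of :func:`vmr_to_concentration` (returns ppbv)."""
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be > 0")
    return mol_m3 * R_GAS * temperature / pressure * 1e9


def _molar_outflow(df: pd.DataFrame, species: str) -> np.ndarray:
    """Outlet molar flow of a species, mol s^-1, per sample."""
    col = f"vmr_{species}"
    if col not in df.columns:
        raise KeyError(f"series lacks column {col!r}")
    q = lpm_to_m3s(df["flow_lpm"].to_numpy())
    n_air = df["pressure_Pa"].to_numpy() / (R_GAS * df["temperature_K"].to_numpy())
    return df[col].to_numpy() * 1e-9 * q * n_air


def _phase(df: pd.DataFrame, phase: str, light: str | None = None) -> pd.DataFrame:
    sel = df["phase"] == phase
    if light is not None:
        sel &= df["light"] == light
    out = df[sel]
    if out.empty:
        where = phase if light is None else f"{phase}/{light}"
        raise MissingPhaseError(f"series has no samples for phase {where!r}")
    return out


def _single_flux(df: pd.DataFrame, species: str, light: str) -> float:
    """Phi for one replicate series, nmol m^-2 s^-1 (deposition < 0)."""
    la = float(df["leaf_area_m2"].iloc[0])
    if la <= 0:
        raise ValueError("leaf_area_m2 must be > 0")
    bg = _phase(df, "background")
    plant = _phase(df, "plant", light)
    f_bg = float(np.mean(_molar_outflow(bg, species)))
    f_plant = float(np.mean(_molar_outflow(plant, species)))
    # background - plant > 0 means the plant removed gas => deposition, Phi < 0
    return -(f_bg - f_plant) / la * 1e9


def compute_flux(series: pd.DataFrame | Sequence[pd.DataFrame], species: str,
                 light: str = "light") -> FluxEstimate:
    """Exchange flux of ``species`` for one light condition.

    ``series`` may be a single frame or a list of replicate frames; the
    replicate spread provides the uncertainty.  Raises
    :class:`MissingPhaseError` when the plant or background phase is
    absent, naming the missing phase.
    """
    frames = [series] if isinstance(series, pd.DataFrame) else list(series)
    if not frames:
        raise ValueError("no series given")
    vals = np.array([_single_flux(df, species, light) for df in frames])
    unc = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return FluxEstimate(species, light, float(np.mean(vals)), unc, len(vals))


def plant_phase_concentration(series: pd.DataFrame | Sequence[pd.DataFrame],
                              species: str, light: str = "light") -> float:
    """Mean gas concentration at the enclosure outlet during the plant
    phase (mol m^-3) — the ambient concentration of the v_d definition."""
    frames = [series] if isinstance(series, pd.DataFrame) else list(series)
    means = []
    for df in frames:
        plant = _phase(df, "plant", light)
        c = (plant[f"vmr_{species}"].to_numpy() * 1e-9
             * plant["pressure_Pa"].to_numpy()
             / (R_GAS * plant["temperature_K"].to_numpy()))
        means.append(float(np.mean(c)))
    return float(np.mean(means))


def compute_deposition_velocity(flux: FluxEstimate, ambient_conc: float | Concentration,
                                ) -> DepositionVelocity:
    """v_d = -Phi / c, in cm s^-1 (positive for net deposition).

    ``ambient_conc`` is in mol m^-3 (or a :class:`Concentration`); the
    flux carries nmol m^-2 s^-1 with the deposition-negative convention.
    """
    c = ambient_conc.mol_m3 if isinstance(ambient_conc, Concentration) else float(ambient_conc)
    if c <= 0:
        raise ValueError("ambient concentration must be > 0 (v_d undefined at c = 0)")
    # nmol m^-2 s^-1 / (mol m^-3) = 1e-9 m s^-1 => * 1e-9 * 100 for cm s^-1
    vd = -flux.flux * 1e-9 / c * 100.0
    unc = flux.uncertainty * 1e-9 / c * 100.0
    return DepositionVelocity(flux.species, vd, flux.condition, unc)


def estimate_deposition_velocity(series: pd.DataFrame | Sequence[pd.DataFrame],
                                 species: str, light: str = "light") -> DepositionVelocity:
    """Full Eq.-1 pipeline: flux from the outlet deficit, then v_d
    against the plant-phase outlet concentration."""
    flux = compute_flux(series, species, light)
    c = plant_phase_concentration(series, species, light)
    return compute_deposition_velocity(flux, c)


def estimate_conversion_yield(series: pd.DataFrame | Sequence[pd.DataFrame],
                              parent: str, product: str,
                              light: str = "light") -> YieldEstimate:
    """Molar conversion yield: product emission over parent deposition.

    Requires the parent to net-deposit (Phi < 0); a yield above 1 is
    reported as-is with ``exceeds_unity`` set.
    """
    frames = [series] if isinstance(series, pd.DataFrame) else list(series)
    vals = []
    for df in frames:
        dep = _single_flux(df, parent, light)
        if abs(dep) < 1e-12 or dep > 0:
            raise ValueError(
                f"parent {parent!r} does not net-deposit in the {light} phase; yield undefined")
        emi = _single_flux(df, product, light)
        vals.append(max(emi, 0.0) / (-dep))
    arr = np.array(vals)
    unc = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    mean = float(np.mean(arr))
    return YieldEstimate(parent, product, light, mean, unc, len(arr),
                         exceeds_unity=mean > 1.0)


def summarize_boxstats(values: Iterable[float]) -> dict[str, float]:
    """Box-plot order statistics: median, quartiles (linear
    interpolation), minimum and maximum."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_boxstats requires at least one value")
    return {
        "median": float(np.median(arr)),
        "q25": float(np.quantile(arr, 0.25)),   # linear interpolation (numpy default)
        "q75": float(np.quantile(arr, 0.75)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
    }


def analyze_enclosure(series: Sequence[pd.DataFrame], parent: str,
                      products: Sequence[str] = (),
                      registry: SpeciesRegistry = REGISTRY) -> pd.DataFrame:
    """Tidy summary over both light conditions.

    Returns one row per (species, condition) with flux, v_d and — for
    the products — the molar conversion yield.
    """
    rows = []
    for light in ("dark", "light"):
        try:
            vd = estimate_deposition_velocity(series, parent, light)
            flux = compute_flux(series, parent, light)
        except MissingPhaseError:
            continue
        rows.append({"species": registry[parent].name, "condition": light,
                     "flux_nmol_m2_s": flux.flux, "flux_sd": flux.uncertainty,
                     "vd_cm_s": vd.vd, "vd_sd": vd.uncertainty,
                     "yield": np.nan, "yield_sd": np.nan, "n": flux.n})
        for product in products:
            y = estimate_conversion_yield(series, parent, product, light)
            pflux = compute_flux(series, product, light)
            rows.append({"species": registry[product].name, "condition": light,
                         "flux_nmol_m2_s": pflux.flux, "flux_sd": pflux.uncertainty,
                         "vd_cm_s": np.nan, "vd_sd": np.nan,
                         "yield": y.value, "yield_sd": y.uncertainty, "n": y.n})
    return pd.DataFrame(rows)
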