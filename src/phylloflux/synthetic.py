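"""Synthetic input generators with known ground truth.

Every pipeline stage consumes data that an instrument would normally
provide: enclosure fumigation time series, 10-Hz eddy-covariance series,
enzyme assay absorbance traces and gridded annual deposition fields.
The generators here emulate each of these with prescribed truth so the
estimators can be validated end to end:

* enclosure series follow the well-mixed flushed-chamber mass balance at
  quasi-steady state per phase, with day/night cycling of the deposition
  velocity and multiplicative lognormal measurement noise;
* eddy-covariance series carry a prescribed kinematic flux as the
  covariance between an AR(1) vertical wind and a lag-shifted scalar;
* assay traces decline linearly at the Michaelis-Menten initial rate
  with additive Gaussian absorbance noise;
* deposition fields distribute prescribed global totals over a grid.

All randomness flows from an explicit integer seed via
``numpy.random.default_rng``; identical scenario + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .budget import BudgetInputs
from .constants import ATM_PA, T_STANDARD, air_molar_density, cms_to_ms, lpm_to_m3s
from .enclosure import SERIES_META_COLUMNS
from .species import REGISTRY, SpeciesRegistry


class ScenarioError(ValueError):
    """A scenario fails physical validation."""


# ---------------------------------------------------------------------------
# enclosure fumigation


@dataclass(frozen=True)
class EnclosureScenario:
    """Ground truth for a fumigation experiment.

    The default numbers mirror the laboratory design: ~8 ppbv of
    1,2-ISOPOOH in the inlet stream, five biological replicates, a 12-h
    photoperiod, and prescribed day/dark deposition velocities.
    """

    species: str = "isopooh_12"
    true_vd_day: float = 0.79        # cm s^-1
    true_vd_night: float = 0.12      # cm s^-1
    yield_map: dict[str, float] = field(default_factory=lambda: {"mvk": 0.5, "mek": 0.5})
    inlet_vmr: float = 8.0           # ppbv
    flow: float = 10.0               # L min^-1
    leaf_area: float = 0.1           # m^2, single-sided
    chamber_volume: float = 10.0     # L
    photoperiod_hours: float = 12.0
    noise_cv: float = 0.02
    n_replicates: int = 5
    background_loss_frac: float = 0.02   # residual wall loss of the conditioned
                                         # empty enclosure, as an inlet fraction
    temperature: float = T_STANDARD  # K
    pressure: float = ATM_PA         # Pa
    samples_per_phase: int = 60
    dt: float = 30.0                 # s between samples
    seed: int = 0

    def validate(self) -> None:
        if self.flow <= 0 or self.leaf_area <= 0 or self.chamber_volume <= 0:
            raise ScenarioError("flow, leaf_area and chamber_volume must be > 0")
        if self.true_vd_day < 0 or self.true_vd_night < 0:
            raise ScenarioError("deposition velocities must be >= 0")
        if self.inlet_vmr < 0 or self.noise_cv < 0:
            raise ScenarioError("inlet_vmr and noise_cv must be >= 0")
        if not 0.0 <= self.background_loss_frac < 1.0:
            raise ScenarioError("background_loss_frac must lie in [0, 1)")
        for product, y in self.yield_map.items():
            if not 0.0 <= y <= 1.0:
                raise ScenarioError(f"yield for {product} outside [0, 1]")
        if sum(self.yield_map.values()) > 1.0 + 1e-12:
            raise ScenarioError("yields must sum to <= 1")
        if self.n_replicates < 1 or self.samples_per_phase < 1:
            raise ScenarioError("n_replicates and samples_per_phase must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with relative spread ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_enclosure_series(scenario: EnclosureScenario,
                         registry: SpeciesRegistry = REGISTRY) -> list[pd.DataFrame]:
    """Generate one enclosure series per replicate.

    Each series has four phases — inlet sampling, empty-enclosure
    background, plant/dark and plant/light — at the quasi-steady state of
    the well-mixed chamber balance.  The residual wall loss of the
    conditioned empty enclosure acts upstream of the plant (in series),
    so the plant removes gas from the background-corrected stream and the
    downstream mass-balance estimator is exact at zero noise:

        c_bg    = (1 - loss) * c_in
        c_plant = c_bg * Q / (Q + v_d * A)
        c_prod  = yield * v_d * A * c_plant / Q
    """
    scenario.validate()
    parent = registry[scenario.species].name
    products = list(scenario.yield_map)
    q = lpm_to_m3s(scenario.flow)
    c_in = scenario.inlet_vmr
    c_bg = c_in * (1.0 - scenario.background_loss_frac)

    def plant_levels(vd_cms: float) -> dict[str, float]:
        k = cms_to_ms(vd_cms) * scenario.leaf_area
        c_parent = c_bg * q / (q + k)
        out = {parent: c_parent}
        for p, y in scenario.yield_map.items():
            out[registry[p].name] = y * k * c_parent / q
        return out

    phases = [
        ("inlet", "dark", {parent: c_in, **{registry[p].name: 0.0 for p in products}}),
        ("background", "dark", {parent: c_bg, **{registry[p].name: 0.0 for p in products}}),
        ("plant", "dark", plant_levels(scenario.true_vd_night)),
        ("plant", "light", plant_levels(scenario.true_vd_day)),
    ]

    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_replicates)
    n = scenario.samples_per_phase
    replicates = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        rows: dict[str, list] = {c: [] for c in SERIES_META_COLUMNS}
        species_cols = {f"vmr_{s}": [] for s in [parent] + [registry[p].name for p in products]}
        t0 = 0.0
        for phase, light, levels in phases:
            t = t0 + scenario.dt * np.arange(n)
            t0 = t[-1] + scenario.dt
            rows["time_s"].extend(t)
            rows["phase"].extend([phase] * n)
            rows["light"].extend([light] * n)
            rows["flow_lpm"].extend([scenario.flow] * n)
            rows["leaf_area_m2"].extend([scenario.leaf_area] * n)
            rows["temperature_K"].extend([scenario.temperature] * n)
            rows["pressure_Pa"].extend([scenario.pressure] * n)
            for col in species_cols:
                sp = col.removeprefix("vmr_")
                level = levels.get(sp, 0.0)
                noisy = level * _lognormal_factor(rng, scenario.noise_cv, n)
                species_cols[col].extend(noisy)
        df = pd.DataFrame({**rows, **species_cols})
        replicates.append(df)
    return replicates


# ---------------------------------------------------------------------------
# eddy covariance


@dataclass(frozen=True)
class ECScenario:
    """Ground truth for a high-frequency flux time series.

    ``true_flux`` and ``mean_vmr`` are per species (nmol m^-2 s^-1 and
    ppbv).  The scalar series lags the wind by ``lag_samples`` samples,
    emulating the travel time through a long sampling tube.
    """

    true_flux: dict[str, float] = field(default_factory=lambda: {"isoprene": 10.0, "mek": 0.18})
    sigma_w: float = 0.5             # m s^-1
    lag_samples: int = 15
    sample_rate: float = 10.0        # Hz
    duration: float = 1800.0         # s
    mean_vmr: dict[str, float] = field(default_factory=lambda: {"isoprene": 2.0, "mek": 0.5})
    noise_cv: float = 0.02
    ar1_coeff: float = 0.9           # wind autocorrelation at one sample
    temperature: float = T_STANDARD
    pressure: float = ATM_PA
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ScenarioError("sample_rate and duration must be > 0")
        if self.duration * self.sample_rate < 2 * abs(self.lag_samples):
            raise ScenarioError("series too short for the requested lag")
        if self.sigma_w <= 0:
            raise ScenarioError("sigma_w must be > 0")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ScenarioError("ar1_coeff must lie in [0, 1)")


def gen_ec_series(scenario: ECScenario) -> pd.DataFrame:
    """Generate a 10-Hz-style eddy-covariance series.

    The vertical wind is a zero-mean AR(1) process with standard
    deviation ``sigma_w``.  Each scalar is built as
    ``mean + a * w[t - lag]`` with ``a`` chosen so that the aligned
    covariance ``cov(w, c)`` times the molar density of air equals the
    prescribed flux, then degraded with multiplicative noise.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration * scenario.sample_rate))
    phi = scenario.ar1_coeff
    innov = rng.normal(0.0, scenario.sigma_w * np.sqrt(1 - phi**2), size=n + 200)
    w = np.empty(n + 200)
    w[0] = rng.normal(0.0, scenario.sigma_w)
    for i in range(1, n + 200):
        w[i] = phi * w[i - 1] + innov[i]
    w = w[200:]                      # discard burn-in
    w -= w.mean()

    n_air = air_molar_density(scenario.temperature, scenario.pressure)
    lag = scenario.lag_samples
    data = {"time_s": np.arange(n) / scenario.sample_rate, "w_ms": w}
    for sp, flux in scenario.true_flux.items():
        a = flux / (n_air * scenario.sigma_w**2)   # ppbv per (m s^-1)
        shifted = np.roll(w, lag)                  # scalar lags the wind
        if lag > 0:
            shifted[:lag] = 0.0
        elif lag < 0:
            shifted[lag:] = 0.0
        c = scenario.mean_vmr.get(sp, 1.0) + a * shifted
        c = c * _lognormal_factor(rng, scenario.noise_cv, n)
        data[f"vmr_{sp}"] = c
    data["temperature_K"] = np.full(n, scenario.temperature)
    data["pressure_Pa"] = np.full(n, scenario.pressure)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# enzyme assays


@dataclass(frozen=True)
class AssayScenario:
    """Ground truth for spectrophotometric AOR assays.

    The default grids bracket the Michaelis constants of MVK and NADPH
    so the downstream fit is identifiable in both substrates.
    """

    vmax: float = 0.05               # mM min^-1
    km_mvk: float = 14.15            # mM
    km_nadph: float = 0.049          # mM
    t_opt: float = 35.0              # deg C
    t_width: float = 10.0            # deg C
    substrate_grid: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0)
    cofactor_grid: tuple[float, ...] = (0.01, 0.025, 0.05, 0.1, 0.2)
    temperatures: tuple[float, ...] = (35.0,)
    absorbance_noise_sd: float = 0.002  # AU
    duration: float = 2.0            # min per trace
    n_points: int = 25
    path_length: float = 1.0         # cm
    seed: int = 0

    def validate(self) -> None:
        if any(s < 0 for s in self.substrate_grid) or any(c < 0 for c in self.cofactor_grid):
            raise ScenarioError("concentrations must be >= 0")
        if self.km_mvk <= 0 or self.km_nadph <= 0:
            raise ScenarioError("Km values must be > 0")
        if self.vmax < 0 or self.absorbance_noise_sd < 0:
            raise ScenarioError("vmax and absorbance_noise_sd must be >= 0")

    def params(self) -> kinetics.KineticParameters:
        return kinetics.KineticParameters(self.vmax, self.km_mvk, self.km_nadph,
                                          self.t_opt, self.t_width)


def gen_assay_traces(scenario: AssayScenario) -> list[kinetics.AssayTrace]:
    """Generate declining A340 traces over the concentration grid.

    Traces start at the absorbance of the supplied NADPH and decline at
    the initial-rate slope ``-epsilon * path * v(S, N, T)``, with
    additive Gaussian noise.  Only the initial-rate regime is emulated
    (no substrate-depletion curvature).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    params = scenario.params()
    eps = kinetics.EPSILON_NADPH_340
    t = np.linspace(0.0, scenario.duration, scenario.n_points)
    traces = []
    for temp in scenario.temperatures:
        for s in scenario.substrate_grid:
            for nconc in scenario.cofactor_grid:
                slope = kinetics.assay_slope(params, s, nconc, temp,
                                             scenario.path_length, eps)
                a0 = eps * scenario.path_length * nconc
                absorbance = a0 + slope * t
                absorbance = absorbance + rng.normal(
                    0.0, scenario.absorbance_noise_sd, size=t.size)
                traces.append(kinetics.AssayTrace(
                    time=t.copy(), absorbance=absorbance, mvk_conc=s,
                    nadph_conc=nconc, temperature=temp,
                    path_length=scenario.path_length, epsilon_nadph=eps))
    return traces


# ---------------------------------------------------------------------------
# gridded deposition fields


def gen_budget_fields(n_lat: int, n_lon: int, totals: BudgetInputs,
                      seed: int = 0) -> pd.DataFrame:
    """Distribute global deposition totals over an n_lat x n_lon grid.

    Cell weights are independent exponential draws normalised to one, so
    fields are nonnegative and their sums equal the requested totals to
    floating-point rounding.
    """
    if n_lat < 1 or n_lon < 1:
        raise ScenarioError("n_lat and n_lon must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_lat * n_lon
    lats = np.repeat(np.linspace(-90 + 90 / n_lat, 90 - 90 / n_lat, n_lat), n_lon)
    lons = np.tile(np.linspace(-180 + 180 / n_lon, 180 - 180 / n_lon, n_lon), n_lat)
    out = {"lat": lats, "lon": lons}
    for name, total in (("dep_mvk", totals.dep_mvk), ("dep_isopooh", totals.dep_isopooh)):
        if total < 0:
            raise ScenarioError(f"{name} total must be >= 0")
        weights = rng.exponential(1.0, size=n)
        out[name] = total * weights / weights.sum()
    return pd.DataFrame(out)
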