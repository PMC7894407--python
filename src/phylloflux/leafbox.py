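"""Dynamic two-compartment leaf uptake-conversion-re-emission model.

A fumigated plant enclosure is modelled as a well-mixed chamber gas
phase coupled to the leaf's apoplast liquid through a stomatal +
cuticular conductance.  Dissolved 1,2-ISOPOOH is cleaved by a
Fenton-type first-order reaction into MVK + HCHO (1:1:1), and dissolved
MVK is reduced to MEK by the NADPH-dependent AOR enzyme
(Michaelis-Menten, with the NADPH pool light-dependent: zero in the
dark).  MVK and MEK, being weakly soluble, volatilise back through the
stomata; HCHO is retained in the liquid phase.

Chamber balance (per species i, concentrations mol m^-3):

    V dC_i/dt = Q (c_in,i - C_i) - g_i A (C_i - C_eq,i)

with C_eq,i the gas-side concentration in Henry equilibrium with the
apoplast, C_eq = (c_aq / H*) * p_atm / (R T).  Apoplast balance
(concentrations M, volume V_aq = apoplast_volume_per_area * A):

    V_aq dc_aq,i/dt = g_i A (C_i - C_eq,i) / 1000 * 1000 + reactions

Because the Fenton step splits one molecule into two, conservation is
checked on carbon atoms (C5 -> C4 + C1; the AOR step is C4 -> C4):
gas + liquid + cumulative outflow - cumulative inflow carbon is constant.

An optional stress response closes stomata smoothly once the dissolved
hydroperoxide passes a threshold, reproducing the observed rebound of
enclosure ISOPOOH after stomatal closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from . import enclosure
from .constants import ATM_PA, R_GAS, T_STANDARD, cms_to_ms, lpm_to_m3s
from .kinetics import KineticParameters
from .species import REGISTRY, SpeciesRegistry

#: Species tracked by the box model, in state-vector order.
BOX_SPECIES = ("isopooh_12", "mvk", "mek", "hcho")
_IDX = {s: i for i, s in enumerate(BOX_SPECIES)}


class IntegrationError(RuntimeError):
    """The stiff integrator failed or produced a negative state."""


@dataclass(frozen=True)
class LeafBoxParams:
    """Physical, physiological and kinetic parameters of the leaf box."""

    chamber_volume: float = 10.0          # L
    flow: float = 10.0                    # L min^-1
    leaf_area: float = 0.1                # m^2, single-sided
    apoplast_volume_per_area: float = 0.05  # L m^-2
    gs_day: float = 0.67                  # stomatal conductance, cm s^-1
    gs_night: float = 0.0                 # cm s^-1
    g_cuticle: float = 0.12               # cm s^-1
    k_fenton: float = 0.01                # s^-1, liquid-phase ISOPOOH cleavage
    aor: KineticParameters = field(
        default_factory=lambda: KineticParameters(29.0, 14.15, 0.049))
    nadph_pool: float = 0.15              # mM in the light; 0 in the dark
    temperature: float = T_STANDARD       # K
    pressure: float = ATM_PA              # Pa
    # stress response (off unless stress_threshold is finite)
    stress_threshold: float = float("inf")  # M dissolved ISOPOOH
    stress_floor: float = 0.02            # cm s^-1, residual gs after closure
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("chamber_volume", "flow", "leaf_area", "apoplast_volume_per_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gs_day", "gs_night", "g_cuticle", "k_fenton", "nadph_pool",
                     "stress_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LeafBoxState:
    """Gas and apoplast state at one instant."""

    gas_vmr: dict[str, float]     # ppbv
    aqueous_conc: dict[str, float]  # M
    time: float = 0.0             # s
    carbon_in: float = 0.0        # cumulative mol C through the inlet
    carbon_out: float = 0.0       # cumulative mol C through the outlet

    @classmethod
    def zero(cls) -> "LeafBoxState":
        return cls({s: 0.0 for s in BOX_SPECIES}, {s: 0.0 for s in BOX_SPECIES})

    def carbon_total(self, params: LeafBoxParams,
                     registry: SpeciesRegistry = REGISTRY) -> float:
        """Carbon in both compartments plus net outflow, mol C.

        Constant along any trajectory (the conservation diagnostic).
        """
        v_m3 = params.chamber_volume / 1000.0
        v_aq = params.apoplast_volume_per_area * params.leaf_area
        n_air = params.pressure / (R_GAS * params.temperature)
        total = self.carbon_out - self.carbon_in
        for s in BOX_SPECIES:
            nc = registry[s].n_carbon
            total += nc * self.gas_vmr[s] * 1e-9 * n_air * v_m3
            total += nc * self.aqueous_conc[s] * v_aq
        return total


def effective_stomatal_conductance(aq_isopooh: float, params: LeafBoxParams,
                                   light: bool) -> float:
    """Stomatal conductance (cm s^-1) with the optional stress response.

    A Hill-type factor 1 / (1 + (c/threshold)^2) closes stomata smoothly
    toward ``stress_floor`` as dissolved ISOPOOH exceeds the threshold;
    an infinite threshold disables the feature, a zero threshold pins gs
    at the floor.
    """
    gs = params.gs_day if light else params.gs_night
    if np.isinf(params.stress_threshold):
        return gs
    floor = min(params.stress_floor, gs)
    if params.stress_threshold == 0.0:
        return floor
    factor = 1.0 / (1.0 + (aq_isopooh / params.stress_threshold) ** 2)
    return floor + (gs - floor) * factor


def _rhs(t, y, params: LeafBoxParams, inlet_conc: np.ndarray, light: bool,
         registry: SpeciesRegistry):
    ns = len(BOX_SPECIES)
    gas = y[:ns]                     # mol m^-3
    aq = y[ns:2 * ns]                # M
    v_m3 = params.chamber_volume / 1000.0
    v_aq = params.apoplast_volume_per_area * params.leaf_area   # L
    q = lpm_to_m3s(params.flow)
    a = params.leaf_area
    gas_factor = ATM_PA / (R_GAS * params.temperature)

    gs = effective_stomatal_conductance(aq[_IDX["isopooh_12"]], params, light)
    g_leaf = cms_to_ms(gs + params.g_cuticle)

    dgas = np.empty(ns)
    daq = np.empty(ns)
    transfer = np.empty(ns)          # mol s^-1, positive = into the leaf
    for i, s in enumerate(BOX_SPECIES):
        g_i = 0.0 if s == "hcho" else g_leaf      # HCHO retained in the liquid
        c_eq = aq[i] / registry[s].henry_eff * gas_factor
        transfer[i] = g_i * a * (gas[i] - c_eq)
        dgas[i] = (q * (inlet_conc[i] - gas[i]) - transfer[i]) / v_m3
        daq[i] = transfer[i] / v_aq

    fenton = params.k_fenton * aq[_IDX["isopooh_12"]]            # M s^-1
    nadph = params.nadph_pool if light else 0.0
    aor_p = params.aor
    s_mm = aq[_IDX["mvk"]] * 1000.0                              # mM
    v_aor = (aor_p.vmax * s_mm / (aor_p.km_mvk + s_mm)
             * nadph / (aor_p.km_nadph + nadph)) / 6.0e4         # mM/min -> M/s

    daq[_IDX["isopooh_12"]] -= fenton
    daq[_IDX["mvk"]] += fenton - v_aor
    daq[_IDX["mek"]] += v_aor
    daq[_IDX["hcho"]] += fenton

    ncarb = np.array([registry[s].n_carbon for s in BOX_SPECIES], dtype=float)
    d_in = q * float(np.dot(ncarb, inlet_conc))
    d_out = q * float(np.dot(ncarb, gas))
    return np.concatenate([dgas, daq, [d_in, d_out]])


def _state_to_vector(state: LeafBoxState, params: LeafBoxParams) -> np.ndarray:
    n_air = params.pressure / (R_GAS * params.temperature)
    gas = np.array([state.gas_vmr[s] * 1e-9 * n_air for s in BOX_SPECIES])
    aq = np.array([state.aqueous_conc[s] for s in BOX_SPECIES])
    return np.concatenate([gas, aq, [state.carbon_in, state.carbon_out]])


def _vector_to_state(y: np.ndarray, t: float, params: LeafBoxParams) -> LeafBoxState:
    ns = len(BOX_SPECIES)
    n_air = params.pressure / (R_GAS * params.temperature)
    gas = {s: float(y[i] / n_air * 1e9) for i, s in enumerate(BOX_SPECIES)}
    aq = {s: float(y[ns + i]) for i, s in enumerate(BOX_SPECIES)}
    return LeafBoxState(gas, aq, t, float(y[2 * ns]), float(y[2 * ns + 1]))


def step(state: LeafBoxState, params: LeafBoxParams,
         inlet_vmr: dict[str, float], dt: float, light: bool = True,
         registry: SpeciesRegistry = REGISTRY,
         t_eval: Sequence[float] | None = None,
         ) -> LeafBoxState | list[LeafBoxState]:
    """Advance the box by ``dt`` seconds under fixed inlet and light.

    Uses the LSODA stiff integrator (the Henry-constant contrast between
    ISOPOOH and the carbonyls makes the system stiff).  Returns the end
    state, or the states at ``t_eval`` (relative times) when given.
    Integration failure or a negative state raises
    :class:`IntegrationError` rather than clamping silently.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_air = params.pressure / (R_GAS * params.temperature)
    cin = np.array([inlet_vmr.get(s, 0.0) * 1e-9 * n_air for s in BOX_SPECIES])
    y0 = _state_to_vector(state, params)
    sol = solve_ivp(_rhs, (0.0, dt), y0, method="LSODA",
                    t_eval=None if t_eval is None else np.asarray(t_eval),
                    args=(params, cin, light, registry),
                    rtol=params.rtol, atol=params.atol)
    if not sol.success:
        raise IntegrationError(f"leaf box integration failed: {sol.message}")
    ns = len(BOX_SPECIES)
    if np.min(sol.y[:2 * ns]) < -1e3 * params.atol:
        raise IntegrationError("integration produced a negative concentration")
    if t_eval is None:
        return _vector_to_state(sol.y[:, -1], state.time + dt, params)
    return [_vector_to_state(sol.y[:, k], state.time + sol.t[k], params)
            for k in range(sol.t.size)]


@dataclass(frozen=True)
class FumigationProgram:
    """Light program for a simulated fumigation experiment."""

    species: str = "isopooh_12"
    inlet_vmr: float = 8.0                # ppbv
    phases: tuple[tuple[str, float], ...] = (("dark", 2500.0), ("light", 2500.0))
    samples_per_phase: int = 20
    settle_fraction: float = 0.75         # sample only the quasi-steady tail


def simulate_fumigation(params: LeafBoxParams, program: FumigationProgram,
                        registry: SpeciesRegistry = REGISTRY,
                        initial: LeafBoxState | None = None,
                        ) -> tuple[pd.DataFrame, LeafBoxState]:
    """Run the light program and emit an enclosure-schema series.

    The output frame contains inlet and background rows (the model
    chamber itself has no wall loss, so the empty-enclosure background
    equals the inlet) followed by the plant-phase samples from the
    quasi-steady tail of each phase, and feeds directly into the
    enclosure estimators.  Also returns the final state, whose
    :meth:`LeafBoxState.carbon_total` serves as the conservation check.
    """
    parent = registry[program.species].name
    if parent not in BOX_SPECIES:
        raise KeyError(f"box model does not track species {parent!r}")
    state = initial if initial is not None else LeafBoxState.zero()
    inlet = {parent: program.inlet_vmr}
    n = program.samples_per_phase

    meta = {"flow_lpm": params.flow, "leaf_area_m2": params.leaf_area,
            "temperature_K": params.temperature, "pressure_Pa": params.pressure}
    rows = []
    for phase in ("inlet", "background"):
        for k in range(n):
            row = {"time_s": float(k), "phase": phase, "light": "dark", **meta}
            for s in BOX_SPECIES:
                row[f"vmr_{s}"] = program.inlet_vmr if s == parent else 0.0
            rows.append(row)

    for light_name, duration in program.phases:
        settle = program.settle_fraction * duration
        t_eval = np.linspace(settle, duration, n)   # quasi-steady tail incl. the end
        states = step(state, params, inlet, duration, light=(light_name == "light"),
                      registry=registry, t_eval=t_eval)
        for st in states:
            row = {"time_s": st.time, "phase": "plant", "light": light_name, **meta}
            for s in BOX_SPECIES:
                row[f"vmr_{s}"] = st.gas_vmr[s]
            rows.append(row)
        state = states[-1]                          # continues into the next phase
    df = pd.DataFrame(rows)
    df["time_s"] = np.arange(len(df), dtype=float)  # monotone sampling axis
    return df, state


@dataclass
class CalibrationResult:
    params: LeafBoxParams
    residual: float              # sum of squared relative target errors
    achieved: dict[str, float]
    targets: dict[str, float]
    success: bool
    message: str = ""


def forward_targets(params: LeafBoxParams,
                    registry: SpeciesRegistry = REGISTRY) -> dict[str, float]:
    """Exchange quantities the calibration matches, computed through the
    fumigation simulator and the enclosure estimators.

    vd_day / vd_night and the MVK/MEK yields come from a dark+light
    1,2-ISOPOOH fumigation; the MVK-fumigation MEK yield is also
    reported (diagnostic; ~1 whenever MEK volatilises freely).
    """
    prog = FumigationProgram(species="isopooh_12")
    series, _ = simulate_fumigation(params, prog, registry)
    vd_night = enclosure.estimate_deposition_velocity(series, "isopooh_12", "dark").vd
    vd_day = enclosure.estimate_deposition_velocity(series, "isopooh_12", "light").vd
    y_mvk = enclosure.estimate_conversion_yield(series, "isopooh_12", "mvk", "light").value
    y_mek = enclosure.estimate_conversion_yield(series, "isopooh_12", "mek", "light").value
    prog_mvk = FumigationProgram(species="mvk", phases=(("light", 2500.0),))
    series_mvk, _ = simulate_fumigation(params, prog_mvk, registry)
    y_mek_from_mvk = enclosure.estimate_conversion_yield(
        series_mvk, "mvk", "mek", "light").value
    return {"vd_day": vd_day, "vd_night": vd_night, "yield_mvk": y_mvk,
            "yield_mek": y_mek, "yield_mek_from_mvk": y_mek_from_mvk}


def _initial_guess(targets: dict[str, float], params: LeafBoxParams,
                   registry: SpeciesRegistry) -> dict[str, float]:
    """Closed-form start: conductances from the velocities, AOR vmax
    from the steady-state volatilisation/reduction balance."""
    g_cut = max(targets["vd_night"], 1e-3)
    gs_day = max(targets["vd_day"] - g_cut, 1e-3)
    r = targets["yield_mek"] / max(targets["yield_mvk"] + targets["yield_mek"], 1e-9)
    g_day_ms = cms_to_ms(gs_day + g_cut)
    ga = g_day_ms * params.leaf_area
    k_volat = (ga * ATM_PA / (R_GAS * params.temperature * registry["mvk"].henry_eff)
               / (1.0 + ga / lpm_to_m3s(params.flow)))  # mol/s per M, net of
    # chamber build-up: emitted MVK accumulates in the chamber and partly
    # re-enters the leaf, so only the flushed fraction escapes
    v_aq = params.apoplast_volume_per_area * params.leaf_area               # L
    f_n = params.nadph_pool / (params.aor.km_nadph + params.nadph_pool)
    aor_per_vmax = (1000.0 / params.aor.km_mvk) * f_n / 6.0e4 * v_aq        # mol/s per M per vmax
    vmax = k_volat * r / max(1.0 - r, 1e-6) / aor_per_vmax
    return {"gs_day": gs_day, "g_cuticle": g_cut, "k_fenton": params.k_fenton,
            "aor_vmax": max(vmax, 1e-3)}


def _apply_free(params: LeafBoxParams, names: Sequence[str],
                values: np.ndarray) -> LeafBoxParams:
    updates: dict = {}
    for name, v in zip(names, values):
        if name == "aor_vmax":
            updates["aor"] = replace(params.aor, vmax=float(v))
        else:
            updates[name] = float(v)
    return replace(params, **updates)


def calibrate(targets: dict[str, float], params: LeafBoxParams = LeafBoxParams(),
              free: Sequence[str] = ("gs_day", "g_cuticle", "k_fenton", "aor_vmax"),
              registry: SpeciesRegistry = REGISTRY,
              tolerance: float = 1e-4, maxiter: int = 400) -> CalibrationResult:
    """Fit free leaf-box parameters to measured exchange targets.

    ``targets`` supplies vd_day, vd_night (cm s^-1) and the molar yields
    of MVK and MEK from deposited 1,2-ISOPOOH.  Bounded Nelder-Mead
    minimises the sum of squared relative mismatches computed through
    :func:`simulate_fumigation` + the enclosure estimators.  Infeasible
    targets yield a result with ``success=False`` and the achieved
    residual, not an exception.  Identifiability is partial (at steady
    state the Fenton rate sets timescales, not the targets), so the fit
    recovers the forward targets rather than unique parameters.
    """
    required = {"vd_day", "vd_night", "yield_mvk", "yield_mek"}
    missing = required - targets.keys()
    if missing:
        raise KeyError(f"targets missing {sorted(missing)}")
    if not (targets["vd_day"] >= targets["vd_night"] >= 0):
        raise ValueError("need vd_day >= vd_night >= 0")
    if targets["yield_mvk"] + targets["yield_mek"] > 1.0 + 1e-9:
        raise ValueError("yields must sum to <= 1")

    guess = _initial_guess(targets, params, registry)
    x0 = np.array([guess[n] for n in free])
    bounds = [(1e-4, 10.0) if n != "aor_vmax" else (0.0, 1e5) for n in free]
    keys = sorted(required)

    def objective(x: np.ndarray) -> float:
        trial = _apply_free(params, free, x)
        try:
            achieved = forward_targets(trial, registry)
        except (IntegrationError, ValueError):
            return 1e6
        return sum(((achieved[k] - targets[k]) / max(abs(targets[k]), 1e-6)) ** 2
                   for k in keys)

    res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8})
    fitted = _apply_free(params, free, res.x)
    achieved = forward_targets(fitted, registry)
    residual = float(res.fun)
    ok = residual < tolerance
    message = "converged" if ok else (
        f"residual {residual:.3g} above tolerance {tolerance:g}; "
        "targets may be infeasible for this parameterisation")
    return CalibrationResult(fitted, residual, achieved, dict(targets), ok, message)
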