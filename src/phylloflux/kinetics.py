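"""Two-substrate Michaelis-Menten kinetics of the NADPH-dependent
alkenal/one oxidoreductase (AOR) that reduces MVK to MEK.

The rate law is multiplicative in the two saturation factors with a
single-optimum temperature response g(T), normalised to 1 at the optimum:

    v(S, N, T) = vmax * S/(Km_S + S) * N/(Km_N + N) * g(T)
    g(T) = exp(-(T - T_opt)^2 / (2 * t_width^2))

S is the MVK concentration, N the NADPH concentration (both mM).  Assays
monitor NADPH consumption as declining absorbance at 340 nm; the initial
trace slope is -epsilon * path * v, so kinetic parameters are fitted by
nonlinear least squares on initial slopes across a concentration (and
optionally temperature) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import EPSILON_NADPH_340


@dataclass(frozen=True)
class KineticParameters:
    vmax: float               # mM min^-1
    km_mvk: float             # mM
    km_nadph: float           # mM
    t_opt: float = 35.0       # deg C
    t_width: float = 10.0     # deg C, breadth of the temperature response

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        if self.km_mvk <= 0 or self.km_nadph <= 0:
            raise ValueError("Km values must be > 0")
        if self.t_width <= 0:
            raise ValueError("t_width must be > 0")


@dataclass
class AssayTrace:
    """One spectrophotometric A340 time course with its conditions."""

    time: np.ndarray          # min
    absorbance: np.ndarray    # AU
    mvk_conc: float           # mM
    nadph_conc: float         # mM
    temperature: float = 35.0  # deg C
    path_length: float = 1.0  # cm
    epsilon_nadph: float = EPSILON_NADPH_340  # AU mM^-1 cm^-1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.mvk_conc < 0 or self.nadph_conc < 0:
            raise ValueError("concentrations must be >= 0")

    def initial_slope(self) -> float:
        """Least-squares slope of the trace, AU min^-1."""
        return float(stats.linregress(self.time, self.absorbance).slope)


@dataclass
class KineticFit:
    params: KineticParameters
    stderr: dict[str, float]
    converged: bool
    residual: float
    n_traces: int = 0
    message: str = ""
    fitted_temperature: bool = False
    extras: dict = field(default_factory=dict)


def temperature_response(temperature, t_opt: float, t_width: float):
    """Gaussian single-optimum response, g(t_opt) = 1."""
    t = np.asarray(temperature, dtype=float)
    return np.exp(-((t - t_opt) ** 2) / (2.0 * t_width**2))


def rate(params: KineticParameters, mvk: float, nadph: float,
         temperature: float | None = None):
    """Reaction velocity v(S, N, T) in mM min^-1."""
    s = np.asarray(mvk, dtype=float)
    n = np.asarray(nadph, dtype=float)
    if np.any(s < 0) or np.any(n < 0):
        raise ValueError("substrate and cofactor concentrations must be >= 0")
    g = 1.0 if temperature is None else temperature_response(
        temperature, params.t_opt, params.t_width)
    v = params.vmax * s / (params.km_mvk + s) * n / (params.km_nadph + n) * g
    return float(v) if np.isscalar(mvk) and np.isscalar(nadph) else v


def assay_slope(params: KineticParameters, mvk: float, nadph: float,
                temperature: float | None = None, path_length: float = 1.0,
                epsilon_nadph: float = EPSILON_NADPH_340) -> float:
    """Predicted dA340/dt (AU min^-1) for the given assay conditions.

    NADPH absorbs at 340 nm and is consumed 1:1 with MVK reduction, so
    the control without MVK has zero slope.
    """
    return -epsilon_nadph * path_length * rate(params, mvk, nadph, temperature)


def recommended_cofactor_conc(km_nadph: float, factor: float = 3.0,
                              decimals: int = 2) -> float:
    """Saturating assay NADPH concentration: ``factor`` times Km,
    rounded to the pipetting precision."""
    if km_nadph <= 0:
        raise ValueError("km_nadph must be > 0")
    return round(factor * km_nadph, decimals)


def fit_kinetics(traces: list[AssayTrace]) -> KineticFit:
    """Fit AOR kinetic parameters to a set of assay traces.

    Initial slopes are extracted per trace and fitted with
    :func:`scipy.optimize.curve_fit` against the two-substrate rate law.
    The temperature optimum and width are additionally fitted when the
    design spans at least three distinct temperatures; otherwise g(T) is
    held at 1 (iso-thermal design).

    Raises ``ValueError`` for a rank-deficient design (fewer than two
    distinct concentrations of either substrate); non-convergence is
    flagged on the result, not raised.
    """
    if not traces:
        raise ValueError("no traces to fit")
    s = np.array([t.mvk_conc for t in traces])
    n = np.array([t.nadph_conc for t in traces])
    temps = np.array([t.temperature for t in traces])
    eps_path = np.array([t.epsilon_nadph * t.path_length for t in traces])
    slopes = np.array([t.initial_slope() for t in traces])
    v_obs = -slopes / eps_path

    if np.unique(s[s > 0]).size < 2 or np.unique(n[n > 0]).size < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct nonzero "
                         "concentrations of both MVK and NADPH")
    fit_temp = np.unique(temps).size >= 3

    def model_iso(x, vmax, km_s, km_n):
        ss, nn = x
        return vmax * ss / (km_s + ss) * nn / (km_n + nn)

    def model_temp(x, vmax, km_s, km_n, t_opt, t_width):
        ss, nn, tt = x
        return (vmax * ss / (km_s + ss) * nn / (km_n + nn)
                * temperature_response(tt, t_opt, t_width))

    v_scale = max(float(np.max(v_obs)), 1e-9)
    try:
        if fit_temp:
            p0 = [v_scale, np.median(s[s > 0]), np.median(n[n > 0]),
                  float(temps[np.argmax(v_obs)]), 10.0]
            popt, pcov = optimize.curve_fit(
                model_temp, (s, n, temps), v_obs, p0=p0,
                bounds=([0, 1e-9, 1e-9, -50, 1e-3], [np.inf] * 3 + [150, 200]),
                maxfev=20000)
            names = ("vmax", "km_mvk", "km_nadph", "t_opt", "t_width")
            pred = model_temp((s, n, temps), *popt)
            params = KineticParameters(*popt)
        else:
            p0 = [v_scale, np.median(s[s > 0]), np.median(n[n > 0])]
            popt, pcov = optimize.curve_fit(
                model_iso, (s, n), v_obs, p0=p0,
                bounds=([0, 1e-9, 1e-9], [np.inf] * 3), maxfev=20000)
            names = ("vmax", "km_mvk", "km_nadph")
            pred = model_iso((s, n), *popt)
            params = KineticParameters(popt[0], popt[1], popt[2])
        converged, message = True, "converged"
    except RuntimeError as err:          # scipy signals non-convergence this way
        return KineticFit(
            KineticParameters(v_scale, float(np.median(s[s > 0])),
                              float(np.median(n[n > 0]))),
            {}, False, float("inf"), len(traces), f"fit did not converge: {err}")

    stderr = {k: float(se) for k, se in zip(names, np.sqrt(np.diag(pcov)))}
    residual = float(np.sum((v_obs - pred) ** 2))
    return KineticFit(params, stderr, converged, residual, len(traces),
                      message, fitted_temperature=fit_temp)
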