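"""Eddy-covariance flux processing.

The vertical turbulent flux of a scalar is the covariance of vertical
wind fluctuations w' with mixing-ratio fluctuations c' over an averaging
window (default 30 min), after despiking, lag correction for the
sampling-line travel time, and block-mean detrending:

    F = <w' c'> * n_air          [m s^-1 * ppbv * mol m^-3 -> nmol m^-2 s^-1]

(the ppbv 1e-9 and the nmol 1e9 cancel).  Emission ratios are ratios of
window-mean fluxes, in percent.

Series are :class:`pandas.DataFrame` objects with columns
``time_s, w_ms, vmr_<species>..., temperature_K, pressure_Pa`` at a
uniform sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import air_molar_density


@dataclass(frozen=True)
class LagResult:
    lag: int                   # samples (scalar lags the wind by this much)
    peak_covariance: float
    significant: bool


@dataclass(frozen=True)
class ECFluxResult:
    species: str
    flux: float                # nmol m^-2 s^-1
    lag: int                   # samples
    averaging_window: float    # s
    n_windows: int
    window_fluxes: np.ndarray = field(repr=False, default=None)
    qc_flags: frozenset = frozenset()

    @property
    def uncertainty(self) -> float:
        """Standard error of the mean across windows."""
        if self.window_fluxes is None or len(self.window_fluxes) < 2:
            return float("nan")
        return float(np.std(self.window_fluxes, ddof=1) / np.sqrt(len(self.window_fluxes)))


def despike(values: np.ndarray, window: int = 300,
            mad_threshold: float = 7.0) -> tuple[np.ndarray, int]:
    """Median/MAD despiking.

    Points deviating from the rolling median by more than
    ``mad_threshold`` scaled median absolute deviations are replaced by
    that median.  A zero MAD (constant stretches) flags nothing.
    Returns the cleaned series and the number of replaced points.
    """
    if window <= 10:
        raise ValueError("despike window must exceed 10 samples")
    x = pd.Series(np.asarray(values, dtype=float))
    med = x.rolling(window, center=True, min_periods=1).median()
    mad = (x - med).abs().rolling(window, center=True, min_periods=1).median()
    scale = 1.4826 * mad
    with np.errstate(invalid="ignore"):
        mask = (x - med).abs() > mad_threshold * scale
    mask &= scale > 0
    cleaned = x.where(~mask, med).to_numpy()
    return cleaned, int(mask.sum())


def _crosscov(w: np.ndarray, c: np.ndarray, lag: int) -> float:
    """cov(w[t], c[t + lag]) of the mean-removed series."""
    n = len(w)
    wp = w - w.mean()
    cp = c - c.mean()
    if lag >= 0:
        a, b = wp[: n - lag], cp[lag:]
    else:
        a, b = wp[-lag:], cp[: n + lag]
    return float(np.mean(a * b))


def find_lag(w: np.ndarray, c: np.ndarray, max_lag: int = 100) -> LagResult:
    """Locate the sampling-line lag by cross-covariance maximisation.

    Searches lags in [-max_lag, max_lag]; ties break toward the smallest
    |lag|.  Significance compares the peak against the white-noise
    standard error sigma_w * sigma_c / sqrt(n) at z = 4 (Bonferroni-ish
    guard over the searched lags); an insignificant peak flags a
    low-confidence lag.
    """
    w = np.asarray(w, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(w) != len(c):
        raise ValueError("series lengths differ")
    if len(w) <= 4 * max_lag:
        raise ValueError("series too short for the requested lag window")
    lags = sorted(range(-max_lag, max_lag + 1), key=abs)   # smallest |lag| first
    covs = {k: _crosscov(w, c, k) for k in lags}
    best = max(lags, key=lambda k: abs(covs[k]))           # first max wins ties
    se = float(np.std(w) * np.std(c) / np.sqrt(len(w)))
    significant = abs(covs[best]) > 4.0 * se if se > 0 else False
    return LagResult(best, covs[best], significant)


def covariance_flux(series: pd.DataFrame, species: str, window: float = 1800.0,
                    max_lag: int = 100, mad_threshold: float = 7.0,
                    min_valid_fraction: float = 0.5) -> ECFluxResult:
    """Window-averaged eddy-covariance flux for one species.

    The scalar is despiked, aligned to the wind by the cross-covariance
    lag (estimated once over the whole series), then the flux is the
    block-mean-detrended covariance per window converted with the
    ideal-gas molar density of air.  Windows with fewer than
    ``min_valid_fraction`` valid samples are skipped with a QC flag.
    """
    col = f"vmr_{species}"
    if col not in series.columns:
        raise KeyError(f"series lacks column {col!r}")
    t = series["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("series too short")
    dt = float(np.median(np.diff(t)))
    w = series["w_ms"].to_numpy(dtype=float)
    c = series[col].to_numpy(dtype=float)
    flags = set()

    c, n_spikes = despike(c, mad_threshold=mad_threshold)
    if n_spikes:
        flags.add("despiked")

    lag_res = find_lag(w, c, max_lag=max_lag)
    if not lag_res.significant:
        flags.add("lag_low_confidence")
    lag = lag_res.lag
    # align: the scalar lags the wind, so shift it back
    if lag > 0:
        w_al, c_al, t_al = w[:-lag], c[lag:], t[:-lag]
    elif lag < 0:
        w_al, c_al, t_al = w[-lag:], c[:lag], t[-lag:]
    else:
        w_al, c_al, t_al = w, c, t

    n_air = air_molar_density(float(series["temperature_K"].iloc[0]),
                              float(series["pressure_Pa"].iloc[0]))
    per_window = int(round(window / dt))
    fluxes = []
    valid = np.isfinite(w_al) & np.isfinite(c_al)
    for start in range(0, len(w_al), per_window):
        sl = slice(start, min(start + per_window, len(w_al)))
        v = valid[sl]
        # a trailing partial window counts if it still holds enough samples
        if v.sum() < min_valid_fraction * per_window:
            flags.add("window_skipped")
            continue
        wp = w_al[sl][v] - np.mean(w_al[sl][v])   # block-mean detrend
        cp = c_al[sl][v] - np.mean(c_al[sl][v])
        fluxes.append(float(np.mean(wp * cp)) * n_air)
    if not fluxes:
        raise ValueError("no window passed quality control")
    arr = np.asarray(fluxes)
    return ECFluxResult(species, float(np.mean(arr)), lag, window, len(arr),
                        window_fluxes=arr, qc_flags=frozenset(flags))


def emission_ratio(flux_num: ECFluxResult, flux_den: ECFluxResult,
                   ) -> tuple[float, float]:
    """Ratio of window-mean fluxes, percent, with window-spread
    uncertainty.

    Requires the denominator (e.g. isoprene) flux to be significantly
    positive: its mean must exceed twice its standard error.
    """
    den = flux_den.flux
    se = flux_den.uncertainty
    if not den > 0 or (np.isfinite(se) and den < 2 * se):
        raise ValueError("denominator flux not significantly > 0; ratio undefined")
    ratio = flux_num.flux / den * 100.0
    # window-to-window spread propagated in quadrature
    per_window = flux_num.window_fluxes / den * 100.0
    spread = float(np.std(per_window, ddof=1) / np.sqrt(len(per_window))) \
        if per_window is not None and len(per_window) > 1 else float("nan")
    return ratio, spread
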