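# Methods

## Scope and structure

`phylloflux` quantifies the leaf-level uptake and conversion of isoprene
photooxidation products (1,2-ISOPOOH, MVK) and the resulting global MEK
source. It chains five largely independent computations — enclosure mass
balance, enzyme kinetics, a mechanistic leaf box model, a resistance-based
deposition scheme, eddy-covariance flux processing — into a molar budget
closure, and ships a synthetic-data module that generates every input with
prescribed truth so the whole chain is testable without instrument data.

## Enclosure mass balance

A plant in a well-mixed, flushed enclosure at quasi-steady state obeys

    Q·c_in = Q·c_out + v_d·A·c_out

so the exchange flux of species *i* is estimated from the molar-flow
difference between the plant outlet and the empty-enclosure (background)
outlet, normalised by single-sided leaf area:

    Φ_i = (F_out,BG − F_out,plant) / LA,     F = vmr·10⁻⁹ · pQ/(RT)

with the sign convention that deposition gives Φ < 0, and

    v_d,i = −Φ_i / c_i  > 0 for net deposition,

where c_i is the plant-phase outlet concentration (the concentration the
leaf actually sees in a well-mixed chamber). Conversion yields are molar
flux ratios, product emission over parent deposition, per light condition.
Background molar flows (not mixing ratios) are subtracted so that runs with
different flows remain comparable. Uncertainties are standard deviations
across biological replicates (default N = 5), matching how replicate spread
is normally reported for such experiments; box-plot summaries use
linear-interpolation quartiles.

The synthetic generator produces the same quasi-steady phases (inlet,
background, plant dark/light) from the identical chamber balance, with the
residual wall loss of the conditioned empty enclosure applied **in series
upstream** of plant uptake. This choice makes the background correction of
the estimator exact: the alternative (wall loss acting in parallel with the
plant at the lower plant-phase concentration) introduces a bias of order
loss/Q that has nothing to do with the estimator under test. Measurement
noise is multiplicative lognormal (unit mean, prescribed CV), the simplest
instrument-like structure consistent with strictly positive mixing ratios.
Day/night cycling is a binary switch on the prescribed deposition velocity,
since only dark/illuminated states are distinguished experimentally.
Chamber volume deliberately does not affect the generated steady state —
only the residence time, which the quasi-steady sampling integrates out.

## AOR enzyme kinetics

The AOR reduction of MVK is modelled as a multiplicative two-substrate
Michaelis–Menten law with a single-optimum temperature response:

    v(S, N, T) = v_max · S/(K_S + S) · N/(K_N + N) · g(T),
    g(T) = exp(−(T − T_opt)² / (2·σ_T²)),  g(T_opt) = 1.

The multiplicative form is the minimal law consistent with independently
measured Michaelis constants for substrate and cofactor; an ordered
bi-bi mechanism is not distinguishable from it with initial-slope data and
is not attempted. The temperature response is only constrained by the
existence of an optimum (35 °C); a normalised Gaussian with configurable
width (default 10 °C) is the minimal single-optimum shape and is isolated
behind one function.

Assays monitor NADPH consumption at 340 nm; the predicted trace slope is
−ε·ℓ·v with ε = 6.22 AU mM⁻¹ cm⁻¹ (standard NADPH molar absorptivity,
configurable) and ℓ the path length. Fitting is nonlinear least squares
(`scipy.optimize.curve_fit`) on **initial slopes** rather than full progress
curves — this matches the assay design and avoids modelling substrate
depletion; the synthetic traces correspondingly emulate only the
initial-rate regime (linear decline plus additive Gaussian absorbance
noise). T_opt and σ_T join the fit only when the design spans at least
three temperatures. Designs with fewer than two distinct concentrations of
either substrate are rejected as rank-deficient; non-convergence is flagged
on the result, never silent.

## Leaf box model

Two compartments: well-mixed chamber gas and apoplast liquid, coupled per
species by a transfer flux g·A·(C − C_eq), with C_eq = (c_aq/H\*)·p_atm/RT
the gas-side concentration in Henry equilibrium with the liquid. The leaf
conductance is stomatal (light-dependent) plus cuticular in parallel; the
boundary layer is folded into the stomatal term because the chamber is
well mixed. Liquid-phase chemistry: first-order Fenton-type cleavage
ISOPOOH → MVK + HCHO (rate k_f·c_aq), and AOR reduction MVK → MEK at the
Michaelis–Menten rate with the NADPH pool held constant in the light and
zero in the dark (light supplies the reductant; no pool dynamics are
resolved). HCHO is kept entirely in the liquid phase (its effective
solubility is high and no formaldehyde emission is observed), and no
finer anatomical structure (mesophyll, cytosol) is resolved.

Because the cleavage step turns one molecule into two, conservation is
checked on **carbon atoms** (C5 → C4 + C1; C4 → C4): chamber + apoplast +
cumulative outflow − cumulative inflow carbon is constant, and every
integration is required to close this balance to 10⁻⁶ relative (achieved:
~10⁻¹⁵). Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹² — the H\*
contrast between ISOPOOH (1.7 × 10⁶) and the carbonyls (44, 21 M atm⁻¹)
spans five orders of magnitude in equilibration timescales, which makes
the system stiff. Negative states abort with an error rather than being
clamped.

The steady-state structure explains the observed exchange: ISOPOOH
re-volatilisation is negligible (< 1% of uptake) because of its enormous
H\*, so v_d ≈ g_s + g_cut; the MVK/MEK split of converted ISOPOOH is the
competition between MVK volatilisation and AOR reduction; and MVK
fumigation returns ~100% MEK at steady state because net-deposited MVK has
nowhere else to go once the apoplast pools are stationary.

**Calibration** adjusts (g_s,day, g_cut, k_f, v_max) by bounded Nelder–Mead
on the summed squared relative mismatch of four targets (day/night v_d and
the two ISOPOOH yields), each computed through the full forward path
(fumigation simulation → enclosure estimators). Identifiability is partial
by construction — at steady state k_f sets timescales, not targets — so the
contract is recovery of the forward targets, not of unique parameters. The
closed-form initial guess uses v_d,night ≈ g_cut, v_d,day − v_d,night ≈ g_s,
and the volatilisation/reduction balance corrected for chamber build-up
(emitted MVK partly re-enters the leaf; only the flushed fraction
Q/(Q + gA) escapes). Apoplast volume per leaf area is not measured; the
default 0.05 L m⁻² is a configured assumption that calibration absorbs —
sweeps over it change calibrated parameters, not achieved targets.

An optional stress response closes stomata smoothly (Hill-type factor,
exponent 2) toward a residual floor once dissolved ISOPOOH exceeds a
threshold; it reproduces qualitatively the observed enclosure rebound
(mixing ratio dips under strong uptake, then rises as stomata close) and
is off by default (threshold ∞).

## Resistance-based dry deposition

Standard three-resistance form v_d = 1/(r_a + r_b + r_c), with the surface
resistance the parallel sum of stomatal+mesophyll, cuticular, lower-canopy
and ground branches. Species scaling uses the effective Henry constant and
the reactivity factor f0:

    r_s scaled by √(M/18) (diffusivity), r_m = 1/(H*/3000 + 100·f0),
    r_lu = r_lu,base/(10⁻⁵H* + f0),
    r_cl, r_gs combined from SO2- and O3-reference resistances as
    1/(10⁻⁵H*/r_X,S + f0/r_X,O).

The full land-use lookup tables of the original scheme are reduced to
per-call base resistances supplied via a small config object — the budget
stage consumes deposition *totals*, so a land-type database would be dead
weight. For 1,2-ISOPOOH and MVK over land the laboratory-constrained
constant velocities (0.79/0.12 and 0.22/0.044 cm s⁻¹ day/night) are
provided directly; over ocean the API returns an explicit delegation marker
instead of a number, forcing the caller back to the resistance scheme.
Day/night classification is binary (boolean or a solar-zenith helper).
Absent branches are open circuits; a network with no conducting branch
returns v_d = 0 with a flag rather than raising.

## Eddy-covariance processing

Fluxes are block-averaged covariances: despike the scalar (rolling
median/MAD, threshold 7 scaled MADs; zero-MAD stretches flag nothing),
estimate the sampling-line lag once per series by cross-covariance
maximisation over ±max_lag (ties toward zero; the peak is tested against
the white-noise standard error σ_w·σ_c/√n at z = 4 and flagged
low-confidence if it fails), align, then per 30-min window remove block
means and convert ⟨w′c′⟩ (m s⁻¹ ppbv) to nmol m⁻² s⁻¹ with the ideal-gas
molar density of air. Windows with under 50% valid samples are skipped
with a QC flag. Emission ratios are ratios of window-mean fluxes in
percent, with the denominator required to exceed twice its standard error.
Block-mean detrending (not linear, not recursive) is the simplest
defensible choice and is the only one implemented; no WPL/density or
spectral corrections, coordinate rotation or storage terms are applied.

The synthetic wind is AR(1) (lag-1 coefficient 0.9 at 10 Hz) — enough
autocorrelation to be turbulence-like for covariance recovery without
claiming a realistic spectrum. The scalar is mean + a·w lagged by the tube
delay, with a set so the aligned covariance times molar density equals the
prescribed flux, then degraded with multiplicative noise.

## Global budget

Molar accounting: mek_from_p = dep_p/M_p · yield_p · M_MEK per parent,
summed, and expressed against the isoprene emission on both molar and mass
bases. Molar yields are the basis used throughout: with the measured yields
(100% MVK, 50% ISOPOOH) and deposition totals of 3.7 and 8.8 Tg yr⁻¹ the
molar accounting closes at 6.5 Tg yr⁻¹ MEK (3.81 + 2.69) and a 1.5%
molar recycling fraction against 416 Tg yr⁻¹ isoprene, whereas mass-basis
yields would give ~8.1 Tg yr⁻¹ — both fractions are therefore reported in
every result so the basis is never implicit. Upper/lower bounding scenarios
take their own deposition totals as inputs (the alternative-scheme totals
are not derivable here). The gridded path applies the same arithmetic per
cell; linearity guarantees grid and scalar results agree to rounding.

## Problem sizes and determinism

Default problem sizes are chosen to match the emulated experiments: 5
replicate enclosure series of 60 samples per phase; a 6 × 5 assay
concentration grid bracketing both Michaelis constants; 100 independent
30-min windows at 10 Hz per eddy-covariance scenario; single fumigation
programs of a few thousand seconds per phase for the leaf box (long against
every internal timescale: chamber flush ~1 min, apoplast MVK seconds,
Fenton ~100 s). Every stochastic operation takes an explicit integer seed
and is bit-reproducible; the acceptance script derives all of its seeds
from one command-line seed.

## What the synthetic data does not show

The generators share the estimators' structural assumptions (well-mixed
chamber, quasi-steady phases, initial-rate assay linearity, stationary
AR(1) turbulence). Passing recovery tests therefore demonstrates estimator
correctness and noise robustness, not robustness to chamber inhomogeneity,
wall sorption dynamics, substrate depletion, non-stationary turbulence or
sensor drift — none of which are emulated. The leaf box model resolves no
anatomy beyond one liquid pool, holds NADPH constant, and treats the
50/50 ISOPOOH split as kinetic competition (volatilisation vs. reduction)
rather than a branched chemical step; the data cannot distinguish the two,
and the calibration contract is agreement in the observable targets only.
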