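"""Mass-balance estimators: unit conversions, flux arithmetic, the
flux/concentration ratio definition of v_d, conversion yields and
box-plot statistics."""

import numpy as np
import pandas as pd
import pytest

from phylloflux import enclosure, synthetic
from phylloflux.enclosure import (Concentration, FluxEstimate, MissingPhaseError,
                                  compute_deposition_velocity, compute_flux,
                                  concentration_to_vmr, estimate_conversion_yield,
                                  estimate_deposition_velocity, summarize_boxstats,
                                  vmr_to_concentration)
from phylloflux.species import REGISTRY


def make_series(vmr_bg, vmr_plant, flow=20.0, leaf_area=0.1, temperature=298.0,
                pressure=101325.0, species="isopooh_12", n=5, extra=None):
    """Minimal hand-built series: one background and one light plant phase."""
    rows = []
    for phase, light, level in (("background", "dark", vmr_bg),
                                ("plant", "light", vmr_plant)):
        for k in range(n):
            row = {"time_s": len(rows), "phase": phase, "light": light,
                   "flow_lpm": flow, "leaf_area_m2": leaf_area,
                   "temperature_K": temperature, "pressure_Pa": pressure,
                   f"vmr_{species}": level}
            for sp, lv in (extra or {}).items():
                row[f"vmr_{sp}"] = lv if phase == "plant" else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


class TestUnitConversion:
    def test_zero_maps_to_zero(self):
        assert vmr_to_concentration(0.0, 298.15, 101325.0).mol_m3 == 0.0

    def test_one_ppbv_standard_conditions(self):
        c = vmr_to_concentration(1.0, 298.15, 101325.0)
        assert c.mol_m3 == pytest.approx(4.087e-8, rel=1e-3)

    def test_round_trip_identity(self):
        for vmr in (0.01, 1.0, 8.0, 450e3):
            c = vmr_to_concentration(vmr, 291.0, 98000.0)
            assert concentration_to_vmr(c.mol_m3, 291.0, 98000.0) == \
                pytest.approx(vmr, rel=1e-12)

    def test_mass_view_uses_molar_mass(self):
        c = vmr_to_concentration(1.0, 298.15, 101325.0, REGISTRY["mvk"])
        # 1 g m^-3 == 1 ug cm^-3, so the mass view is mol_m3 * M
        assert c.ug_cm3 == pytest.approx(c.mol_m3 * 70.09)

    def test_negative_vmr_rejected(self):
        with pytest.raises(ValueError):
            vmr_to_concentration(-1.0, 298.0, 101325.0)


class TestFlux:
    def test_no_deficit_no_flux(self):
        flux = compute_flux(make_series(5.0, 5.0), "isopooh_12")
        assert flux.flux == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_magnitude(self):
        # 2 ppbv deficit, 20 L/min, 0.1 m2, 298 K -> |Phi| = 0.273 nmol/m2/s
        flux = compute_flux(make_series(5.0, 3.0), "isopooh_12")
        assert flux.flux == pytest.approx(-0.273, rel=2e-3)

    def test_flux_inversely_proportional_to_leaf_area(self):
        f1 = compute_flux(make_series(5.0, 3.0, leaf_area=0.1), "isopooh_12")
        f2 = compute_flux(make_series(5.0, 3.0, leaf_area=0.05), "isopooh_12")
        assert f2.flux == pytest.approx(2 * f1.flux)

    def test_missing_background_named(self):
        df = make_series(5.0, 3.0)
        with pytest.raises(MissingPhaseError, match="background"):
            compute_flux(df[df.phase != "background"], "isopooh_12")

    def test_replicate_spread_feeds_uncertainty(self):
        series = [make_series(5.0, 3.0), make_series(5.0, 3.2)]
        flux = compute_flux(series, "isopooh_12")
        assert flux.n == 2 and flux.uncertainty > 0


class TestDepositionVelocity:
    def test_zero_flux_zero_velocity(self):
        vd = compute_deposition_velocity(
            FluxEstimate("isopooh_12", "light", 0.0, 0.0, 1), 1e-7)
        assert vd.vd == 0.0

    def test_direct_ratio(self):
        # Phi = -0.12 nmol m^-2 s^-1 against c = 1e-7 mol m^-3
        # -> v_d = 0.12e-9 / 1e-7 m s^-1 = 0.12 cm s^-1
        vd = compute_deposition_velocity(
            FluxEstimate("mvk", "light", -0.12, 0.0, 1), 1e-7)
        assert vd.vd == pytest.approx(0.12)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            compute_deposition_velocity(
                FluxEstimate("mvk", "light", -0.1, 0.0, 1), 0.0)

    def test_eq1_consistency_on_noisefree_truth(self, noisefree_replicate):
        """The full pipeline returns the generator's prescribed v_d
        exactly when no noise is present."""
        df, sc = noisefree_replicate
        vd_day = estimate_deposition_velocity(df, "isopooh_12", "light")
        vd_night = estimate_deposition_velocity(df, "isopooh_12", "dark")
        assert vd_day.vd == pytest.approx(sc.true_vd_day, rel=1e-6)
        assert vd_night.vd == pytest.approx(sc.true_vd_night, rel=1e-6)

    def test_sign_convention(self, noisefree_replicate):
        """Deposition means Phi < 0 and v_d > 0, simultaneously."""
        df, _ = noisefree_replicate
        for light in ("dark", "light"):
            flux = compute_flux(df, "isopooh_12", light)
            vd = estimate_deposition_velocity(df, "isopooh_12", light)
            assert flux.flux < 0 and vd.vd > 0


class TestConversionYield:
    def test_zero_product_emission(self):
        df = make_series(5.0, 3.0, extra={"mvk": 0.0})
        y = estimate_conversion_yield(df, "isopooh_12", "mvk")
        assert y.value == 0.0

    def test_noisefree_yields_match_truth(self, noisefree_replicate):
        df, sc = noisefree_replicate
        for product, truth in sc.yield_map.items():
            y = estimate_conversion_yield(df, "isopooh_12", product, "light")
            assert y.value == pytest.approx(truth, rel=1e-9)

    def test_macr_pathway_produces_no_mek(self):
        """The 4,3 hydroperoxide isomer converts to methacrolein only."""
        sc = synthetic.EnclosureScenario(species="isopooh_43",
                                         yield_map={"macr": 1.0, "mek": 0.0},
                                         noise_cv=0.0, n_replicates=1)
        df = synthetic.gen_enclosure_series(sc)[0]
        y = estimate_conversion_yield(df, "isopooh_43", "mek", "light")
        assert y.value == pytest.approx(0.0, abs=1e-12)
        y_macr = estimate_conversion_yield(df, "isopooh_43", "macr", "light")
        assert y_macr.value == pytest.approx(1.0, rel=1e-9)

    def test_scale_invariance(self, noisefree_replicate):
        """Multiplying every mixing ratio by a constant leaves yields
        unchanged (the estimator is a flux ratio)."""
        df, _ = noisefree_replicate
        scaled = df.copy()
        for col in scaled.filter(like="vmr_").columns:
            scaled[col] *= 3.7
        y0 = estimate_conversion_yield(df, "isopooh_12", "mvk", "light")
        y1 = estimate_conversion_yield(scaled, "isopooh_12", "mvk", "light")
        assert y1.value == pytest.approx(y0.value, rel=1e-12)

    def test_nondepositing_parent_rejected(self):
        df = make_series(5.0, 6.0, extra={"mvk": 0.1})   # parent emitted, not deposited
        with pytest.raises(ValueError, match="net-deposit"):
            estimate_conversion_yield(df, "isopooh_12", "mvk")


class TestEstimatorBias:
    def test_bias_under_instrument_noise(self):
        """<2% bias for v_d and yields across 200 noisy replicates."""
        sc = synthetic.EnclosureScenario(noise_cv=0.02, n_replicates=200, seed=42)
        series = synthetic.gen_enclosure_series(sc)
        vds = [estimate_deposition_velocity(df, "isopooh_12", "light").vd
               for df in series]
        ys = [estimate_conversion_yield(df, "isopooh_12", "mvk", "light").value
              for df in series]
        assert abs(np.mean(vds) - sc.true_vd_day) < 0.02 * sc.true_vd_day
        assert abs(np.mean(ys) - 0.5) < 0.02 * 0.5


class TestBoxStats:
    def test_odd_sample(self):
        s = summarize_boxstats([1, 2, 3, 4, 5])
        assert (s["median"], s["min"], s["max"]) == (3, 1, 5)

    def test_single_value(self):
        s = summarize_boxstats([2.5])
        assert all(v == 2.5 for v in s.values())

    def test_linear_interpolation_quartiles(self):
        s = summarize_boxstats([1, 2, 3, 4])
        assert s["q25"] == pytest.approx(1.75)
        assert s["q75"] == pytest.approx(3.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_boxstats([])


def test_analyze_enclosure_tidy_output(noisy_replicates):
    series, sc = noisy_replicates
    table = enclosure.analyze_enclosure(series, "isopooh_12", ["mvk", "mek"])
    assert set(table["condition"]) == {"dark", "light"}
    row = table[(table.species == "isopooh_12") & (table.condition == "light")]
    assert row["vd_cm_s"].iloc[0] == pytest.approx(sc.true_vd_day, rel=0.05)
    assert (table["n"] == 5).all()
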