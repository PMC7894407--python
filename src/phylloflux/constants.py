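"""Physical constants and unit helpers."""

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Standard atmosphere, Pa.
ATM_PA = 101325.0

#: Standard temperature for lab conditions, K.
T_STANDARD = 298.15

#: NADPH molar absorptivity at 340 nm, AU mM^-1 cm^-1.
EPSILON_NADPH_340 = 6.22


def air_molar_density(temperature: float, pressure: float) -> float:
    """Ideal-gas molar density of air, mol m^-3."""
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be > 0")
    return pressure / (R_GAS * temperature)


def lpm_to_m3s(flow_lpm: float) -> float:
    """Convert a volumetric flow from L min^-1 to m^3 s^-1."""
    return flow_lpm / 6.0e4


def cms_to_ms(v_cms: float) -> float:
    """Convert a velocity from cm s^-1 to m s^-1."""
    return v_cms / 100.0
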