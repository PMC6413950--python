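"""Physical constants and unit helpers.

All external free energies are in kcal/mol; estimator internals work in
dimensionless reduced units (u = U/kT).
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default simulation/assay temperature in kelvin.
DEFAULT_TEMPERATURE = 300.0

#: Standard-state concentration for Ki -> dG conversion, mol/L.
C_STANDARD = 1.0


def kt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
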