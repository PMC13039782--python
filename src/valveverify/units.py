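"""Unit conversion constants.

Everything internal is SI (Pa, m, s, kg).  Clinical units (mmHg, mL, cm^2,
L/min, beats/min) appear only at the I/O boundary.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

CM2_TO_M2 = 1.0e-4
M2_TO_CM2 = 1.0e4

ML_TO_M3 = 1.0e-6
M3_TO_ML = 1.0e6

WATER_DENSITY = 1000.0  # kg/m^3
WATER_DYNAMIC_VISCOSITY = 1.0e-3  # Pa s


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p * PA_TO_MMHG


def stroke_volume_ml(cardiac_output_l_min: float, heart_rate_bpm: float) -> float:
    """Stroke volume in mL from cardiac output (L/min) and heart rate (bpm)."""
    if cardiac_output_l_min <= 0 or heart_rate_bpm <= 0:
        raise ValueError("cardiac output and heart rate must be positive")
    return 1000.0 * cardiac_output_l_min / heart_rate_bpm
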