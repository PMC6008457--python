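"""Physical constants and the small unit conversions used throughout.

Conventions: concentrations in mM, fluxes in µmol/g/h, time in hours,
membrane potential in mV, temperature in K.
"""

from __future__ import annotations

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/mol/K
BODY_TEMPERATURE = 310.15  # K

#: RT/F at body temperature, in mV; the natural voltage scale of the GHK flux.
THERMAL_VOLTAGE_MV = GAS_CONSTANT * BODY_TEMPERATURE / FARADAY * 1000.0

MOLAR_MASS_ETHANOL = 46.07  # g/mol
MOLAR_MASS_GLUCOSE = 180.16  # g/mol

#: mM of dissolved O2 per mmHg partial pressure (Henry's law, plasma, 37 °C).
O2_SOLUBILITY_MM_PER_MMHG = 0.0013

#: Litres of extracellular fluid of a standard adult, used by the
#: bolus-dilution worked example.
STANDARD_EXTRACELLULAR_VOLUME_L = 15.0


class UnknownConversionError(ValueError):
    pass


def ethanol_mm_to_permille(conc_mm: float) -> float:
    """Plasma ethanol concentration (mM) to per-mille (g ethanol / L)."""
    return conc_mm * MOLAR_MASS_ETHANOL / 1000.0


def glucose_g_to_mmol(mass_g: float) -> float:
    """Grams of glucose to mmol."""
    return mass_g / MOLAR_MASS_GLUCOSE * 1000.0


def bolus_dilution_mm(amount_g: float, volume_l: float,
                      molar_mass: float = MOLAR_MASS_GLUCOSE) -> float:
    """Concentration rise (mmol/L) when ``amount_g`` grams dissolve in
    ``volume_l`` litres of distribution volume."""
    if volume_l <= 0:
        raise ValueError("distribution volume must be positive")
    return amount_g / molar_mass * 1000.0 / volume_l


def po2_mmhg_to_mm(po2_mmhg: float) -> float:
    """Partial O2 pressure (mmHg) to dissolved O2 concentration (mM)."""
    return po2_mmhg * O2_SOLUBILITY_MM_PER_MMHG


_CONVERSIONS = {
    "ethanol-permille": lambda v, **kw: ethanol_mm_to_permille(v),
    "glucose-mmol": lambda v, **kw: glucose_g_to_mmol(v),
    "bolus-dilution": lambda v, **kw: bolus_dilution_mm(
        v, kw.get("volume_l", STANDARD_EXTRACELLULAR_VOLUME_L)),
    "po2-mm": lambda v, **kw: po2_mmhg_to_mm(v),
}


def convert_units(kind: str, value: float, **kwargs) -> float:
    """Dispatch a named unit conversion.

    Recognised kinds: ``ethanol-permille`` (mM → per mille),
    ``glucose-mmol`` (g → mmol), ``bolus-dilution`` (g → mM rise, keyword
    ``volume_l``), ``po2-mm`` (mmHg → mM).
    """
    try:
        fn = _CONVERSIONS[kind]
    except KeyError:
        raise UnknownConversionError(
            f"unknown conversion kind {kind!r}; known: {sorted(_CONVERSIONS)}")
    return fn(value, **kwargs)
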