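"""Gas-phase unit arithmetic for NOx species.

Passive samplers report mixing ratios in ppb; health guidelines are stated in
µg/m³.  Conversion uses the ideal-gas molar volume at the measurement week's
temperature (and a fixed default pressure), with species-specific molecular
weights.  NO is not measured directly: it is the molar difference NOx − NO2,
taken in ppb *before* mass conversion, because mass units are not closed under
that subtraction (NOx-as-NO2 conventions differ between reporting networks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: molecular weights, g/mol
MOLECULAR_WEIGHT = {"NO2": 46.0055, "NO": 30.006}

#: ideal gas constant, J/(mol K)
_R = 8.31446261815324

#: standard surface pressure, hPa
STANDARD_PRESSURE_HPA = 1013.25


def molar_volume(temperature_c: float, pressure_hpa: float = STANDARD_PRESSURE_HPA) -> float:
    """Ideal-gas molar volume in litres/mol at the given conditions."""
    if pressure_hpa <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_hpa}")
    t_k = temperature_c + 273.15
    if t_k <= 0:
        raise ValueError(f"temperature below absolute zero: {temperature_c} degC")
    # R T / P : (J mol-1 K-1 * K) / Pa = m3/mol ; * 1000 -> L/mol
    return _R * t_k / (pressure_hpa * 100.0) * 1000.0


def ppb_to_ugm3(
    conc_ppb,
    species: str,
    temperature_c: float = 25.0,
    pressure_hpa: float = STANDARD_PRESSURE_HPA,
):
    """Convert a mixing ratio in ppb to a mass concentration in µg/m³.

    ``conc [µg/m³] = conc [ppb] × MW / V_m`` with V_m the ideal-gas molar
    volume in L/mol at (temperature, pressure).  At 25 °C and 1013.25 hPa this
    gives ≈1.88 µg/m³ per ppb NO2 and ≈1.23 per ppb NO, the factors usually
    quoted for ambient reporting.

    Relative humidity is accepted by some networks as a second correction; no
    humidity correction is applied here (see :func:`humidity_correction` for
    the optional hook).
    """
    try:
        mw = MOLECULAR_WEIGHT[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; expected one of {sorted(MOLECULAR_WEIGHT)}"
        ) from None
    vm = molar_volume(temperature_c, pressure_hpa)
    return np.asarray(conc_ppb, dtype=float) * mw / vm


def humidity_correction(conc_ugm3, rh_percent):
    """Optional humidity-correction hook; identity by default.

    Exposed so a network-specific sampler correction can be slotted in; the
    default conversion is dry ideal-gas.
    """
    return np.asarray(conc_ugm3, dtype=float)


@dataclass
class NOResult:
    """NO mixing ratios derived from NOx − NO2, with a clip indicator."""

    no_ppb: np.ndarray
    clipped: np.ndarray  # True where the raw difference was negative


def derive_no(nox_ppb, no2_ppb) -> NOResult:
    """NO = NOx − NO2 in ppb, clipped at zero.

    Negative differences (measurement noise when NO is near zero) are floored
    at 0 and flagged.
    """
    nox = np.asarray(nox_ppb, dtype=float)
    no2 = np.asarray(no2_ppb, dtype=float)
    diff = nox - no2
    clipped = diff < 0
    return NOResult(no_ppb=np.where(clipped, 0.0, diff), clipped=clipped)
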