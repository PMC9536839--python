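"""Physical constants and nucleus tables used across the package.

Gyromagnetic ratios are carried to 6+ significant figures; ppm <-> rad/s
conversions everywhere derive the heteronucleus Larmor frequency from the
stated 1H spectrometer frequency via these ratios.
"""

from __future__ import annotations

# rad s^-1 T^-1
GAMMA_H1 = 2.67522187e8
GAMMA_C13 = 6.728284e7
GAMMA_N15 = -2.7116e7

# vacuum permeability (T^2 m^3 J^-1), reduced Planck constant (J s)
MU_0 = 1.25663706e-6
HBAR = 1.054571817e-34

#: 13C Larmor frequency as a fraction of the 1H frequency
C13_RATIO = GAMMA_C13 / GAMMA_H1
#: |15N| Larmor frequency as a fraction of the 1H frequency
N15_RATIO = abs(GAMMA_N15) / GAMMA_H1

#: default methyl 2H quadrupolar coupling constant (Hz)
QCC_2H = 167e3

#: entropy-meter slope, kcal/(mol K) per (order-parameter unit * dihedral)
ENTROPY_METER_SLOPE = -0.0011

#: default analysis temperature (K)
T_KELVIN = 298.15

#: ratio of D2O to H2O viscosities at 25 C
D2O_H2O_VISCOSITY_RATIO = 1.235

#: amide N-H bond length (m) and 15N CSA (unitless) for rigid-rotor rates
NH_BOND_LENGTH = 1.02e-10
N15_CSA = -160e-6


def larmor_mhz(spectrometer_1h_mhz: float, nucleus: str) -> float:
    """Larmor frequency (MHz, magnitude) of ``nucleus`` on a spectrometer
    whose 1H frequency is ``spectrometer_1h_mhz``."""
    ratios = {"1H": 1.0, "13C": C13_RATIO, "15N": N15_RATIO}
    try:
        return spectrometer_1h_mhz * ratios[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}") from None


def ppm_to_rad_s(dw_ppm: float, spectrometer_1h_mhz: float, nucleus: str) -> float:
    """Convert a chemical-shift difference in ppm to rad/s for ``nucleus``."""
    import math

    return 2.0 * math.pi * dw_ppm * larmor_mhz(spectrometer_1h_mhz, nucleus)
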