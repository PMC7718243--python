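"""Physical constants and unit conversions for saturation-transfer MRI.

All public functions take offsets in ppm and saturation amplitudes B1 in µT;
angular frequencies are rad/s.
"""

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.675e8

#: Default proton Larmor frequency at 7 T, MHz.
DEFAULT_F0_MHZ = 300.06


def ppm_to_hz(offset_ppm, f0_mhz: float = DEFAULT_F0_MHZ):
    """Chemical-shift offset in ppm -> frequency offset in Hz."""
    return np.asarray(offset_ppm, dtype=float) * f0_mhz


def ppm_to_rad_s(offset_ppm, f0_mhz: float = DEFAULT_F0_MHZ):
    """Chemical-shift offset in ppm -> angular frequency offset in rad/s."""
    return 2.0 * np.pi * ppm_to_hz(offset_ppm, f0_mhz)


def omega1_rad_s(b1_ut) -> float:
    """Saturation amplitude B1 in µT -> nutation angular frequency ω1 = γB1."""
    return GAMMA_H * np.asarray(b1_ut, dtype=float) * 1e-6
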