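"""Physical constants and unit conversions used package-wide.

Internal conventions:

* off-resonance fields are stored in Hz,
* susceptibility gradients in uT/m (scanner frame),
* z-shim gradient moments in mT/m*ms,
* protocol timings and lengths in SI (s, m).
"""

import math

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.6753e8

#: gamma / 2 pi, Hz T^-1 (~42.58 MHz/T).
GAMMA_BAR = GAMMA / (2.0 * math.pi)

#: uT/m -> T/m
UT_PER_M = 1e-6

#: mT/m*ms -> T*s/m (gradient-moment unit used for the z-shim).
MT_PER_M_MS = 1e-6


def hz_per_m_to_ut_per_m(slope_hz_per_m):
    """Convert a spatial field derivative (Hz/m) into a gradient in uT/m."""
    return slope_hz_per_m / GAMMA_BAR / UT_PER_M
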