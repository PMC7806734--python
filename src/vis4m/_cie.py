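"""CIE 1924 2-degree photopic luminous efficiency function V(lambda).

Canonical 5-nm values, 380-780 nm; linearly interpolated to the 1-nm working
grid.  V(555 nm) = 1 exactly, anchoring the candela definition
(683 lm/W at 555 nm).
"""

from __future__ import annotations

import numpy as np

#: Maximum luminous efficacy of radiation, lm/W at 555 nm.
K_M = 683.0

_WL_5NM = np.arange(380.0, 785.0, 5.0)

_V_5NM = np.array([
    0.00004, 0.00006, 0.00012, 0.00022, 0.00040, 0.00064, 0.00121, 0.00218,
    0.00400, 0.00730, 0.01160, 0.01684, 0.02300, 0.02980, 0.03800, 0.04800,
    0.06000, 0.07390, 0.09098, 0.11260, 0.13902, 0.16930, 0.20802, 0.25860,
    0.32300, 0.40730, 0.50300, 0.60820, 0.71000, 0.79320, 0.86200, 0.91485,
    0.95400, 0.98030, 0.99495, 1.00000, 0.99500, 0.97860, 0.95200, 0.91540,
    0.87000, 0.81630, 0.75700, 0.69490, 0.63100, 0.56680, 0.50300, 0.44120,
    0.38100, 0.32100, 0.26500, 0.21700, 0.17500, 0.13820, 0.10700, 0.08160,
    0.06100, 0.04458, 0.03200, 0.02320, 0.01700, 0.01192, 0.00821, 0.00572,
    0.00410, 0.00293, 0.00209, 0.00148, 0.00105, 0.00074, 0.00052, 0.00036,
    0.00025, 0.00017, 0.00012, 0.00008, 0.00006, 0.00004, 0.00003, 0.00002,
    0.00001,
])

assert _WL_5NM.shape == _V_5NM.shape


def photopic_efficiency(wavelength_nm) -> np.ndarray | float:
    """V(lambda); zero outside 380-780 nm."""
    wl = np.asarray(wavelength_nm, dtype=float)
    v = np.interp(wl, _WL_5NM, _V_5NM, left=0.0, right=0.0)
    if np.isscalar(wavelength_nm):
        return float(v)
    return v
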