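"""Physical constants and unit conversions.

Internally the package works in Hartree atomic units throughout
(energy: hartree, time: a.u., dipole: e*a0, field: a.u.).  Interfaces
accept eV for energies/frequencies, fs for times and W/cm^2 for pulse
intensities and convert at the boundary.
"""

from __future__ import annotations

import numpy as np

#: 1 hartree in eV (CODATA 2018).
HARTREE_EV = 27.211386245988

#: 1 atomic unit of time in femtoseconds.
AU_TIME_FS = 0.024188843265857

#: Atomic unit of intensity in W/cm^2: I_au = (1/2) eps0 c E_au^2.
#: A field amplitude F (a.u.) corresponds to intensity F^2 * I_au.
INTENSITY_AU_W_CM2 = 3.50944758e16


def ev_to_hartree(e: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(e) / HARTREE_EV if np.ndim(e) else e / HARTREE_EV


def hartree_to_ev(e: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(e) * HARTREE_EV if np.ndim(e) else e * HARTREE_EV


def fs_to_au(t: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(t) / AU_TIME_FS if np.ndim(t) else t / AU_TIME_FS


def au_to_fs(t: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(t) * AU_TIME_FS if np.ndim(t) else t * AU_TIME_FS
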