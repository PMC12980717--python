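"""Multi-pulse electric fields.

The driving field is a sum of Gaussian-envelope cosine pulses,

    F(t) = sum_i F_i0 * cos(omega * (t - t_i) - phi_i)
                 * exp(-(t - t_i)^2 / (2 delta^2)),

with per-pulse center ``t_i`` and carrier phase ``phi_i``; carrier
frequency ``omega``, width ``delta`` (the Gaussian sigma, no FWHM
reinterpretation) and amplitude vector shared by all pulses of a 2DES
sequence.  All quantities are atomic units internally; constructors
accept fs / eV / W/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import INTENSITY_AU_W_CM2, ev_to_hartree, fs_to_au

__all__ = [
    "Pulse",
    "PulseSequence",
    "field_at",
    "intensity_to_amplitude",
    "sequence_for_scan",
]


@dataclass(frozen=True)
class Pulse:
    """A single Gaussian-envelope cosine pulse (atomic units)."""

    center: float                 # t_i
    omega: float                  # carrier angular frequency == energy (a.u.)
    phase: float                  # phi_i (rad)
    amplitude: np.ndarray         # F_i0, 3-vector (a.u.)
    width: float                  # delta, Gaussian sigma (a.u. time)

    def __post_init__(self) -> None:
        amp = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        if amp.shape != (3,):
            raise ValueError("amplitude must be a 3-vector")
        object.__setattr__(self, "amplitude", amp)
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if self.omega <= 0:
            raise ValueError("carrier frequency must be positive")

    @classmethod
    def from_lab(cls, center_fs: float, omega_ev: float, phase: float,
                 amplitude_au: float, width_fs: float,
                 polarization=(0.0, 0.0, 1.0)) -> "Pulse":
        """Build a pulse from interface units (fs, eV, unit polarization)."""
        pol = np.asarray(polarization, dtype=float)
        pol = pol / np.linalg.norm(pol)
        return cls(fs_to_au(center_fs), ev_to_hartree(omega_ev), phase,
                   amplitude_au * pol, fs_to_au(width_fs))

    def envelope_carrier(self, t) -> np.ndarray:
        """Dimensionless cos * Gaussian factor at time(s) t."""
        dt = np.asarray(t, dtype=float) - self.center
        return np.cos(self.omega * dt - self.phase) * np.exp(
            -dt * dt / (2.0 * self.width**2))

    def field(self, t) -> np.ndarray:
        """Instantaneous field, shape ``t.shape + (3,)``."""
        return np.multiply.outer(self.envelope_carrier(t), self.amplitude)


@dataclass(frozen=True)
class PulseSequence:
    """Ordered pulses plus the lab polarization axis used for signal
    projection.  In 2DES mode all pulses share omega, delta and
    amplitude ("three laser pulses with identical shape")."""

    pulses: tuple[Pulse, ...]
    polarization: np.ndarray = None  # unit 3-vector e_hat

    def __post_init__(self) -> None:
        if not self.pulses:
            raise ValueError("empty pulse sequence")
        centers = [p.center for p in self.pulses]
        if np.any(np.diff(centers) < 0):
            raise ValueError("pulse centers must be non-decreasing")
        if self.polarization is None:
            amp = self.pulses[0].amplitude
            nrm = np.linalg.norm(amp)
            pol = amp / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        else:
            pol = np.asarray(self.polarization, dtype=float)
            pol = pol / np.linalg.norm(pol)
        object.__setattr__(self, "polarization", pol)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.pulses])

    @property
    def phases(self) -> np.ndarray:
        return np.array([p.phase for p in self.pulses])

    def shifted(self, delta_t: float) -> "PulseSequence":
        return PulseSequence(
            tuple(replace(p, center=p.center + delta_t) for p in self.pulses),
            self.polarization)


def field_at(seq: PulseSequence, t) -> np.ndarray:
    """Total instantaneous field of a sequence: the sum over its pulses."""
    out = seq.pulses[0].field(t)
    for p in seq.pulses[1:]:
        out = out + p.field(t)
    return out


def intensity_to_amplitude(intensity_w_cm2: float) -> float:
    """Peak field amplitude (a.u.) for a given intensity in W/cm^2.

    Uses ``F0 = sqrt(I / I_au)`` with the atomic unit of intensity
    ``I_au = 3.50944758e16 W/cm^2``.
    """
    if intensity_w_cm2 < 0:
        raise ValueError("intensity must be non-negative")
    return float(np.sqrt(intensity_w_cm2 / INTENSITY_AU_W_CM2))


def sequence_for_scan(template: Pulse, tau: float, T: float,
                      phases: tuple[float, float, float],
                      t1: float | None = None) -> PulseSequence:
    """Three identical-shape pulses at centers ``t1, t1+tau, t1+tau+T``.

    ``tau`` and ``T`` are the coherence and population delays (a.u.).
    Overlapping pulses (small positive delays) are allowed; negative
    delays are not.  ``t1`` defaults to ``5 * delta`` so the first
    envelope is negligible at the propagation start.
    """
    if tau < 0 or T < 0:
        raise ValueError("delays must be non-negative")
    if t1 is None:
        t1 = 5.0 * template.width
    centers = (t1, t1 + tau, t1 + tau + T)
    pulses = tuple(
        replace(template, center=c, phase=ph)
        for c, ph in zip(centers, phases))
    return PulseSequence(pulses)
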