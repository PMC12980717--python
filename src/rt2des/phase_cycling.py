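"""Phase cycling: isolate phase-matched components of the polarization.

The total polarization from a three-pulse run depends on the carrier
phases ``phi = (phi1, phi2, phi3)`` and admits the Fourier series

    P(t, phi) = sum_{l,m,n} P_lmn(t) * exp(i (l phi1 + m phi2 + n phi3)),

where ``P_lmn`` is the polarization emitted along the phase-matching
direction ``l k1 + m k2 + n k3``.  The rephasing signal is the
``(-1, +1, +1)`` component and the nonrephasing signal ``(+1, -1, +1)``.

The built-in 12-setting scheme (``domcke_engel_12``) keeps ``phi2 = 0``
and combines the 12 phase-dependent polarizations with fixed complex
weights.  Applying the printed weight rows to analytic phase exponentials
shows that, under the series convention above, the ``C_II`` row isolates
the rephasing ``(l, n) = (-1, +1)`` component and the ``C_I`` row the
nonrephasing ``(+1, +1)`` one, each with an overall factor of 8 (hence
normalization 1/8); the scheme is verified against the full-phase-grid
discrete-Fourier oracle in the test suite rather than trusted from
transcription.  Because ``phi2`` is never varied and ``phi1, phi3`` live
on a pi/2 grid, components alias modulo 4 in ``l`` and ``n`` and ``m`` is
not resolved; the aliased partners of the two target components are
higher-order or counter-rotating terms that are negligible for weak
fields and end up on the opposite frequency branch (see docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .active_space import ActiveSpace
from .dynamics import (PropagationConfig, dephasing_channels, draw_jump_plan,
                       propagate_batch, substream, total_jump_rate,
                       _interaction_matrix)
from .fields import Pulse

__all__ = [
    "PhaseCycleScheme",
    "PolarizationSet",
    "domcke_engel_12",
    "run_phase_battery",
    "extract_component",
    "full_grid_decompose",
]

_PI = np.pi

#: Printed 12-setting scheme: phases (phi1, phi2, phi3) per setting.
_PHI1 = np.array([0, 0, .5, .5, 1, 1, 1.5, 0, 0, .5, 1.5, 1.5]) * _PI
_PHI2 = np.zeros(12)
_PHI3 = np.array([0, .5, 1, .5, 0, .5, 1.5, 1.5, 1, 1.5, 1, .5]) * _PI

#: Printed weight rows (typographic "1- i" read as 1 - i).
C_I = np.array([0, 1 - 1j, 1 + 1j, -1, 0, 0, -1, 1 + 1j, -2, -1j, 1 - 1j, 1j])
C_II = np.array([1 + 1j, -1 - 1j, 1 - 1j, 0, -1 - 1j, 1 + 1j, 1 - 1j, 0, 0,
                 -1 + 1j, -1 + 1j, 0])


@dataclass(frozen=True)
class PhaseCycleScheme:
    """Phase settings plus extraction weights for R and NR components."""

    settings: np.ndarray        # (S, 3) phase triples
    weights_R: np.ndarray       # (S,) complex, isolates (-1, +1, +1)
    weights_NR: np.ndarray      # (S,) complex, isolates (+1, -1, +1)
    normalization: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.settings, dtype=float))
        wR = np.asarray(self.weights_R, dtype=complex)
        wNR = np.asarray(self.weights_NR, dtype=complex)
        if s.shape[1] != 3 or wR.shape != (s.shape[0],) or wNR.shape != wR.shape:
            raise ValueError("settings/weights lengths disagree")
        object.__setattr__(self, "settings", s)
        object.__setattr__(self, "weights_R", wR)
        object.__setattr__(self, "weights_NR", wNR)

    @property
    def n_settings(self) -> int:
        return self.settings.shape[0]

    def to_json(self, path: str | Path) -> None:
        data = {
            "name": self.name,
            "settings_pi": (self.settings / _PI).tolist(),
            "weights_R": [[w.real, w.imag] for w in self.weights_R],
            "weights_NR": [[w.real, w.imag] for w in self.weights_NR],
            "normalization": self.normalization,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhaseCycleScheme":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["settings_pi"]) * _PI,
                   np.asarray([complex(a, b) for a, b in data["weights_R"]]),
                   np.asarray([complex(a, b) for a, b in data["weights_NR"]]),
                   data.get("normalization", 1.0), data.get("name", "custom"))


def domcke_engel_12() -> PhaseCycleScheme:
    """The built-in 12-setting scheme with normalization 1/8."""
    return PhaseCycleScheme(np.column_stack([_PHI1, _PHI2, _PHI3]),
                            weights_R=C_II, weights_NR=C_I,
                            normalization=1.0 / 8.0, name="domcke_engel_12")


@dataclass
class PolarizationSet:
    """Per-setting scalar polarization traces of one (tau, T) scan point."""

    tau: float                  # a.u.
    T: float                    # a.u.
    settings: np.ndarray        # (S, 3)
    times: np.ndarray           # (nt,), a.u.
    traces: np.ndarray          # (S, nt), real: P . e_hat

    def __post_init__(self) -> None:
        if self.traces.shape != (self.settings.shape[0], self.times.shape[0]):
            raise ValueError("one trace per setting on a common grid required")


def _battery_batch(space: ActiveSpace, template: Pulse, tau: float, T: float,
                   cfg: PropagationConfig, settings: np.ndarray,
                   pol_axis: np.ndarray | None = None, t1: float | None = None):
    """Build the batch arrays for one (tau, T) point: one field row per
    phase setting, ``n_traj`` trajectories per row for SSE (the same
    noise realizations reused across settings)."""
    if t1 is None:
        t1 = 5.0 * template.width
    S = settings.shape[0]
    centers = np.tile(np.array([t1, t1 + tau, t1 + tau + T]), (S, 1))
    phases = settings.copy()
    n_traj = cfg.n_traj if cfg.method == "sse" else 1
    field_index = np.repeat(np.arange(S), n_traj)
    B = S * n_traj
    n = space.n_states
    C0 = np.zeros((B, n), dtype=complex)
    C0[:, 0] = 1.0
    if pol_axis is None:
        amp = template.amplitude
        nrm = np.linalg.norm(amp)
        pol_axis = amp / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    Mdet = space.dipole_along(pol_axis)
    jump_events = None
    chans = None
    if cfg.method == "sse" and cfg.dephasing_T2 is not None:
        chans = dephasing_channels(space, cfg)
        rate = total_jump_rate(chans)
        n_steps = int(round(cfg.t_final / cfg.dt))
        per_traj = [draw_jump_plan(substream(cfg.seed, j), rate, n_steps, cfg.dt)
                    for j in range(n_traj)]
        jump_events = [per_traj[j] for _ in range(S) for j in range(n_traj)]
    return centers, phases, field_index, C0, Mdet, jump_events, chans, n_traj


def run_phase_battery(space: ActiveSpace, template: Pulse, tau: float,
                      T: float, cfg: PropagationConfig,
                      scheme: PhaseCycleScheme,
                      t1: float | None = None) -> PolarizationSet:
    """One propagation (or SSE trajectory ensemble) per phase setting.

    Returns the scalar polarization ``P . e_hat`` on the stored time
    grid for every setting; SSE traces are ensemble averages, with
    identical jump realizations reused across the settings of this
    (tau, T) point so phase-cycling combinations cancel noise common to
    settings.
    """
    (centers, phases, field_index, C0, Mdet, jump_events,
     chans, n_traj) = _battery_batch(space, template, tau, T, cfg,
                                     scheme.settings, t1=t1)
    n_steps = int(round(cfg.t_final / cfg.dt))
    count = n_steps // cfg.store_stride + 1
    res = propagate_batch(
        space.energies, _interaction_matrix(space, template.amplitude),
        template.omega, template.width, centers, phases, cfg.dt, n_steps,
        C0, field_index=field_index, detect_matrix=Mdet,
        detect_start=np.zeros(C0.shape[0], dtype=np.int64),
        detect_stride=cfg.store_stride, detect_count=count,
        jump_events=jump_events, channels=chans, norm_tol=cfg.norm_tol)
    traces = res["P"].reshape(scheme.n_settings, n_traj, count).mean(axis=1)
    times = np.arange(count) * (cfg.store_stride * cfg.dt)
    return PolarizationSet(tau, T, scheme.settings.copy(), times, traces)


def extract_component(pset: PolarizationSet, scheme: PhaseCycleScheme,
                      which: str) -> np.ndarray:
    """Weighted sum of the per-setting traces: the complex component
    ``P_{-1,+1,+1}(t)`` (``which="R"``) or ``P_{+1,-1,+1}(t)``
    (``which="NR"``), including the scheme normalization."""
    if pset.settings.shape != scheme.settings.shape or \
            not np.allclose(pset.settings, scheme.settings):
        raise ValueError("polarization set was generated under a different scheme")
    if which == "R":
        w = scheme.weights_R
    elif which == "NR":
        w = scheme.weights_NR
    else:
        raise ValueError("which must be 'R' or 'NR'")
    return scheme.normalization * (w @ pset.traces)


def full_grid_decompose(space: ActiveSpace, template: Pulse, tau: float,
                        T: float, cfg: PropagationConfig, n_phase: int,
                        t1: float | None = None) -> dict:
    """Oracle: full ``n_phase**3`` equally spaced phase grid, inverted by
    discrete Fourier transform.

    Returns a dict mapping ``(l, m, n)`` (each in
    ``-n_phase//2 .. n_phase//2``, aliasing-free for band-limited
    signals) to the complex component time series, plus ``"times"``.
    """
    if n_phase < 3:
        raise ValueError("n_phase must be >= 3")
    grid = 2 * _PI * np.arange(n_phase) / n_phase
    p1, p2, p3 = np.meshgrid(grid, grid, grid, indexing="ij")
    settings = np.column_stack([p1.ravel(), p2.ravel(), p3.ravel()])
    (centers, phases, field_index, C0, Mdet, jump_events,
     chans, n_traj) = _battery_batch(space, template, tau, T, cfg, settings,
                                     t1=t1)
    n_steps = int(round(cfg.t_final / cfg.dt))
    count = n_steps // cfg.store_stride + 1
    res = propagate_batch(
        space.energies, _interaction_matrix(space, template.amplitude),
        template.omega, template.width, centers, phases, cfg.dt, n_steps,
        C0, field_index=field_index, detect_matrix=Mdet,
        detect_start=np.zeros(C0.shape[0], dtype=np.int64),
        detect_stride=cfg.store_stride, detect_count=count,
        jump_events=jump_events, channels=chans, norm_tol=cfg.norm_tol)
    traces = res["P"].reshape(n_phase, n_phase, n_phase, n_traj, count)
    traces = traces.mean(axis=3)
    # P_lmn = (1/N^3) sum_phi P(phi) exp(-i (l phi1 + m phi2 + n phi3))
    comp = np.fft.fftn(traces, axes=(0, 1, 2)) / n_phase**3
    out = {"times": np.arange(count) * (cfg.store_stride * cfg.dt)}
    half = n_phase // 2
    for l in range(-half, half + 1):
        for m in range(-half, half + 1):
            for nn in range(-half, half + 1):
                out[(l, m, nn)] = comp[l % n_phase, m % n_phase, nn % n_phase]
    return out
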