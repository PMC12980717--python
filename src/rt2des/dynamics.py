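"""Real-time propagation of the coefficient vector.

The wave function is expanded in the field-free eigenstates,
``|Psi(t)> = sum_lam C_lam(t) |lam>``, and the coefficient vector obeys
``i dC/dt = H(t) C`` with

    H(t)[a, b] = E_b * delta_ab - F(t) . mu[a, b],

integrated with the explicit leapfrog (second-order Euler) scheme

    C(t + dt) = C(t - dt) - 2i dt H(t) C(t).

The missing ``C(-dt)`` is bootstrapped with a single fourth-order Taylor
step of ``exp(+i H(0) dt)`` applied to ``C(0)``.

Open-system dynamics uses the Markovian stochastic Schroedinger equation
with pure-dephasing channels, realized with the Monte-Carlo wave-function
(quantum-jump) algorithm.  Every dephasing channel is diagonal in the
state basis, and for the channel sets built here ``sum_q S_q^dag S_q`` is
proportional to the identity; the deterministic non-Hermitian norm decay
between jumps is therefore integrated exactly as a scalar factor (the
leapfrog scheme itself would be unstable for a non-Hermitian term), and
jump times form a Poisson process whose rate is the total channel rate.

Everything here operates on *batches* of propagations (many scan points /
phase settings / stochastic trajectories as one linear-algebra stream);
the single-trajectory API is the batch of size one, so both paths are
bit-identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .active_space import ActiveSpace
from .fields import Pulse, PulseSequence
from .units import fs_to_au

__all__ = [
    "PropagationConfig",
    "CoefficientTrajectory",
    "DensityMatrixSeries",
    "StabilityError",
    "build_hamiltonian",
    "propagate_tdse",
    "propagate_sse",
    "average_density",
    "polarization",
    "dephasing_channels",
    "dephasing_gamma",
    "coherence_decay_rate",
    "draw_jump_plan",
    "substream",
]


class StabilityError(RuntimeError):
    """Propagation left the stable regime; use a smaller time step."""


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation settings (atomic units internally).

    ``dephasing_T2`` is the user-facing pure-dephasing time: the 1/e
    decay time of any field-free coherence.  With the default
    ``t2_convention="calibrated"`` the per-channel rate gamma is chosen
    so the observed coherence decay time equals T2 exactly
    (``gamma = 1/(2 T2)`` for the per-state channel set, where both
    channels of a state pair contribute).  ``"literal"`` uses
    ``gamma = 1/T2`` as the raw operator-definition mapping.
    """

    dt: float = fs_to_au(0.0242)
    t_final: float = fs_to_au(100.0)
    method: str = "tdse"               # "tdse" | "sse"
    dephasing_T2: float | None = None
    n_traj: int = 1
    seed: int = 0
    store_stride: int = 8
    t2_convention: str = "calibrated"  # "calibrated" | "literal"
    channel_mode: str = "per_state"    # "per_state" | "per_pair"
    include_ground_channel: bool = True
    norm_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_final <= self.dt:
            raise ValueError("t_final must exceed dt")
        if self.method not in ("tdse", "sse"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sse":
            if self.dephasing_T2 is not None and self.dephasing_T2 <= 0:
                raise ValueError("dephasing_T2 must be positive")
            if self.n_traj < 1:
                raise ValueError("n_traj must be >= 1")
        if self.t2_convention not in ("calibrated", "literal"):
            raise ValueError("t2_convention must be 'calibrated' or 'literal'")
        if self.channel_mode not in ("per_state", "per_pair"):
            raise ValueError("channel_mode must be 'per_state' or 'per_pair'")

    @classmethod
    def from_lab(cls, dt_fs: float = 0.0242, t_final_fs: float = 100.0,
                 t2_fs: float | None = None, **kw) -> "PropagationConfig":
        return cls(dt=fs_to_au(dt_fs), t_final=fs_to_au(t_final_fs),
                   dephasing_T2=None if t2_fs is None else fs_to_au(t2_fs),
                   **kw)


@dataclass
class CoefficientTrajectory:
    """Stored expansion coefficients of one propagation/realization."""

    times: np.ndarray                  # (n_stored,), a.u.
    coeffs: np.ndarray                 # (n_stored, n_states), complex
    jump_log: list = dc_field(default_factory=list)  # [(time, channel), ...]
    norm_drift: float = 0.0            # max observed | |C|^2 - 1 |


@dataclass
class DensityMatrixSeries:
    """Trajectory-averaged density matrix rho(t)."""

    times: np.ndarray                  # (n_stored,)
    rho: np.ndarray                    # (n_stored, n, n), hermitian


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------


def build_hamiltonian(space: ActiveSpace, field: np.ndarray) -> np.ndarray:
    """Matrix H = diag(E) - F . mu for an instantaneous field 3-vector."""
    f = np.asarray(field, dtype=float)
    if f.shape != (3,):
        raise ValueError("field must be a 3-vector")
    if not np.all(np.isfinite(f)):
        raise ValueError("field must be finite")
    return np.diag(space.energies) - np.tensordot(space.dipoles, f, axes=([2], [0]))


# ---------------------------------------------------------------------------
# Dephasing channels
# ---------------------------------------------------------------------------


def dephasing_gamma(cfg: PropagationConfig, n_states: int) -> float:
    """Per-channel rate gamma implied by cfg.dephasing_T2 (see class doc)."""
    if cfg.dephasing_T2 is None:
        return 0.0
    if cfg.t2_convention == "literal":
        return 1.0 / cfg.dephasing_T2
    # calibrated: make the field-free coherence 1/e time exactly T2
    if cfg.channel_mode == "per_state":
        # both channels of a pair contribute: rate = 2 gamma
        return 1.0 / (2.0 * cfg.dephasing_T2)
    # per_pair: rate = gamma * n_states / 2 (uniform over pairs)
    return 2.0 / (n_states * cfg.dephasing_T2)


def dephasing_channels(space: ActiveSpace, cfg: PropagationConfig) -> np.ndarray:
    """Diagonal channel operators as rows d_q of shape (M, n).

    per_state (default): one channel per state lam,
    ``S_lam = sqrt(gamma/2) sum_{lam'} D(lam, lam') |lam'><lam'|`` with
    ``D = -1`` iff ``lam' == lam`` and ``+1`` otherwise; a jump flips
    the sign of C_lam, leaving every population untouched.

    per_pair: one channel per state pair (a, b),
    ``S_ab = sqrt(gamma/2) (|a><a| - |b><b|)``.
    """
    n = space.n_states
    gamma = dephasing_gamma(cfg, n)
    root = np.sqrt(gamma / 2.0)
    lo = 0 if cfg.include_ground_channel else 1
    if cfg.channel_mode == "per_state":
        states = list(range(lo, n))
        d = np.full((len(states), n), root)
        for row, lam in enumerate(states):
            d[row, lam] = -root
        return d
    pairs = [(a, b) for a in range(lo, n) for b in range(a + 1, n)]
    d = np.zeros((len(pairs), n))
    for row, (a, b) in enumerate(pairs):
        d[row, a] = root
        d[row, b] = -root
    return d


def coherence_decay_rate(channels: np.ndarray, a: int, b: int) -> float:
    """Exact Lindblad decay rate of the (a, b) coherence for diagonal
    channels: ``(1/2) sum_q (d_q[a] - d_q[b])^2``.  Serves as the
    analytic oracle for the stochastic ensemble."""
    diff = channels[:, a] - channels[:, b]
    return 0.5 * float(np.sum(diff * diff))


def total_jump_rate(channels: np.ndarray) -> float:
    """Norm-loss rate ``<sum_q S_q^dag S_q>`` for the (identity-
    proportional) channel sets built here."""
    s = (channels**2).sum(axis=0)
    if not np.allclose(s, s[0]):
        raise ValueError("channel set is not identity-proportional")
    return float(s[0]) if len(s) else 0.0


def draw_jump_plan(rng: np.random.Generator, rate: float,
                   n_steps: int, dt: float) -> list[tuple[int, float]]:
    """Draw the (step, channel-uniform) jump events of one trajectory.

    Jump times are exponential gaps at the total channel rate (exact for
    identity-proportional ``sum S^dag S``), snapped to the nearest step.
    The second element is the uniform variate used for channel choice at
    event time.
    """
    if rate <= 0:
        return []
    events = []
    t = rng.exponential(1.0 / rate)
    t_total = n_steps * dt
    while t < t_total:
        events.append((int(round(t / dt)), rng.random()))
        t += rng.exponential(1.0 / rate)
    return events


def substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: reproducible RNG for one scan coordinate."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# Batched leapfrog engine
# ---------------------------------------------------------------------------


def _taylor_backward(H: np.ndarray, C: np.ndarray, dt: float) -> np.ndarray:
    """High-order single backward step used to bootstrap C(-dt) and to
    restart the two-step recursion after a quantum jump.

    The leapfrog scheme propagates each eigenmode at the numerical
    frequency ``arcsin(E dt)/dt``; initializing with the physical
    ``exp(+i H dt)`` would excite the parasitic (computational) mode
    with amplitude ~(E dt)^3/6, visible as a norm oscillation.  We
    therefore exponentiate the scheme-matched generator
    ``arcsin(dt H) ~ dt H + (dt H)^3/6`` to fourth order, which keeps
    the parasitic admixture at O((E dt)^5).  ``H``: (..., n, n);
    ``C``: (..., n).
    """
    A = dt * H
    A3 = np.einsum("...ij,...jk,...kl->...il", A, A, A)
    X = 1j * (A + A3 / 6.0)
    term = C.copy()
    out = C.copy()
    for k in range(1, 5):
        term = np.einsum("...ij,...j->...i", X, term) / k
        out = out + term
    return out


def _envelope_factor(t: float, centers: np.ndarray, phases: np.ndarray,
                     omega: float, width: float) -> np.ndarray:
    """Sum over pulses of cos(omega (t - t_i) - phi_i) * gaussian, per
    batch row.  centers/phases: (Bf, n_pulses) -> (Bf,)."""
    d = t - centers
    return np.sum(np.cos(omega * d - phases) * np.exp(d * d * (-0.5 / width**2)),
                  axis=-1)


def propagate_batch(
    energies: np.ndarray,
    V: np.ndarray,
    omega: float,
    width: float,
    centers: np.ndarray,
    phases: np.ndarray,
    dt: float,
    n_steps: int,
    C0: np.ndarray,
    *,
    field_index: np.ndarray | None = None,
    detect_matrix: np.ndarray | None = None,
    detect_start: np.ndarray | None = None,
    detect_stride: int = 1,
    detect_count: int = 0,
    coeff_stride: int | None = None,
    jump_events: Sequence[Sequence[tuple[int, float]]] | None = None,
    channels: np.ndarray | None = None,
    snapshot_step: np.ndarray | None = None,
    norm_tol: float = 1e-3,
    check_every: int = 250,
) -> dict:
    """Propagate a batch of coefficient vectors under the explicit field.

    Parameters
    ----------
    energies, V
        State energies (n,) and the interaction matrix ``F0 . mu``
        evaluated at unit envelope factor, shape (n, n), both real.
    omega, width
        Shared carrier frequency and Gaussian width of all pulses.
    centers, phases
        Per-field-row pulse centers and carrier phases, shape
        (Bf, n_pulses).
    C0
        Initial coefficients, shape (B, n).
    field_index
        Optional (B,) map from batch member to field row (lets many
        stochastic trajectories share one field evaluation).
    detect_*
        If ``detect_matrix`` is given, the scalar polarization
        ``Re <C| detect_matrix |C>`` is recorded for member b at steps
        ``detect_start[b] + k * detect_stride``, k < detect_count.
    coeff_stride
        If given, coefficients are stored every that many steps.
    snapshot_step
        Optional (B,) step indices; the coefficient vector of member b
        is captured when the loop reaches ``snapshot_step[b]`` (before
        any jump scheduled at that step) and returned as ``snapshot``.
    jump_events, channels
        Quantum-jump schedule per member (list of ``(step, u)``) and the
        diagonal channel rows d_q (M, n); at an event the channel is
        chosen with probability ``~ sum_i d_q[i]^2 |C_i|^2`` using u,
        the state is multiplied elementwise by d_q and renormalized, and
        the leapfrog history is re-bootstrapped.

    Returns
    -------
    dict with keys ``P`` (B, detect_count), ``coeffs`` (B, n_stored, n),
    ``times`` (n_stored,), ``norm_drift`` (B,), ``jump_log``.
    """
    E = np.asarray(energies, dtype=float)
    n = E.shape[0]
    C0 = np.asarray(C0, dtype=complex)
    if C0.ndim == 1:
        C0 = C0[None, :]
    B = C0.shape[0]
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if field_index is None:
        if centers.shape[0] not in (1, B):
            raise ValueError("centers rows must match batch or use field_index")
        if centers.shape[0] == 1:
            field_index = np.zeros(B, dtype=np.intp)
        else:
            field_index = np.arange(B, dtype=np.intp)
    else:
        field_index = np.asarray(field_index, dtype=np.intp)

    e_max = float(np.abs(E).max())
    if dt * e_max > 0.9:
        raise StabilityError(
            f"dt * E_max = {dt * e_max:.2f} too large for the leapfrog "
            "scheme; reduce the time step")

    do_detect = detect_matrix is not None
    if do_detect:
        P_out = np.zeros((B, detect_count))
        detect_start = np.asarray(detect_start, dtype=np.int64)
        Mdet = np.asarray(detect_matrix)
    n_stored = (n_steps // coeff_stride + 1) if coeff_stride else 0
    if coeff_stride:
        coeffs_out = np.empty((B, n_stored, n), dtype=complex)
    if snapshot_step is not None:
        snapshot_step = np.asarray(snapshot_step, dtype=np.int64)
        snapshot_out = np.empty((B, n), dtype=complex)

    # jump schedule grouped by step
    events_by_step: dict[int, list[tuple[int, float]]] = {}
    if jump_events is not None:
        for member, ev in enumerate(jump_events):
            for step, u in ev:
                events_by_step.setdefault(step, []).append((member, u))
    jump_log: list[tuple[int, float, int]] = []

    g_row = _envelope_factor(0.0, centers, phases, omega, width)
    H0 = np.diag(E)[None, :, :] - g_row[field_index, None, None] * V[None, :, :]
    C_prev = _taylor_backward(H0, C0, dt)      # C(-dt)
    C_cur = C0.copy()
    norm0 = np.sum(np.abs(C_cur) ** 2, axis=1)
    if np.any(norm0 == 0):
        raise ValueError("zero-norm initial state")
    norm_drift = np.zeros(B)
    two_i_dt = 2j * dt

    for step in range(n_steps + 1):
        t = step * dt
        if coeff_stride and step % coeff_stride == 0:
            coeffs_out[:, step // coeff_stride, :] = C_cur
        if snapshot_step is not None:
            sel = snapshot_step == step
            if np.any(sel):
                snapshot_out[sel] = C_cur[sel]
        if do_detect:
            k = step - detect_start
            sel = (k >= 0) & (k % detect_stride == 0) & (k < detect_count * detect_stride)
            if np.any(sel):
                W = C_cur[sel] @ Mdet
                P_out[sel, k[sel] // detect_stride] = np.einsum(
                    "bi,bi->b", np.conj(C_cur[sel]), W).real
        if step in events_by_step:
            members = events_by_step[step]
            g_now = _envelope_factor(t, centers, phases, omega, width)
            for member, u in members:
                w = (channels**2) @ np.abs(C_cur[member]) ** 2
                q = int(np.searchsorted(np.cumsum(w / w.sum()), u))
                q = min(q, channels.shape[0] - 1)
                C_cur[member] = channels[q] * C_cur[member]
                nrm = np.linalg.norm(C_cur[member])
                if nrm == 0:
                    raise StabilityError("jump produced a zero-norm state")
                C_cur[member] /= nrm
                C_cur[member] *= np.sqrt(norm0[member])
                Hm = np.diag(E) - g_now[field_index[member]] * V
                C_prev[member] = _taylor_backward(Hm, C_cur[member], dt)
                jump_log.append((member, t, q))
        if step % check_every == 0 or step == n_steps:
            dev = np.abs(np.sum(np.abs(C_cur) ** 2, axis=1) / norm0 - 1.0)
            norm_drift = np.maximum(norm_drift, dev)
            if dev.max() > norm_tol:
                raise StabilityError(
                    f"norm deviation {dev.max():.2e} beyond {norm_tol:g} at "
                    f"step {step}; reduce the time step")
        if step == n_steps:
            break
        g = _envelope_factor(t, centers, phases, omega, width)[field_index]
        D = E * C_cur - g[:, None] * (C_cur @ V)
        C_next = C_prev - two_i_dt * D
        C_prev = C_cur
        C_cur = C_next

    out: dict = {"norm_drift": norm_drift, "jump_log": jump_log,
                 "final": C_cur}
    if do_detect:
        out["P"] = P_out
    if snapshot_step is not None:
        out["snapshot"] = snapshot_out
    if coeff_stride:
        out["coeffs"] = coeffs_out
        out["times"] = np.arange(n_stored) * (coeff_stride * dt)
    return out


# ---------------------------------------------------------------------------
# Single-propagation API
# ---------------------------------------------------------------------------


def _sequence_arrays(seq: PulseSequence):
    """Shared (omega, width, amplitude) plus per-pulse centers/phases."""
    p0 = seq.pulses[0]
    for p in seq.pulses[1:]:
        if not (np.isclose(p.omega, p0.omega) and np.isclose(p.width, p0.width)
                and np.allclose(p.amplitude, p0.amplitude)):
            raise ValueError("pulses of a sequence must share shape "
                             "(omega, width, amplitude)")
    return (p0.omega, p0.width, p0.amplitude,
            seq.centers[None, :], seq.phases[None, :])


def _interaction_matrix(space: ActiveSpace, amplitude: np.ndarray) -> np.ndarray:
    return np.tensordot(space.dipoles, amplitude, axes=([2], [0]))


def propagate_tdse(space: ActiveSpace, seq: PulseSequence,
                   cfg: PropagationConfig, C0: np.ndarray) -> CoefficientTrajectory:
    """Closed-system propagation of one coefficient vector."""
    omega, width, amp, centers, phases = _sequence_arrays(seq)
    n_steps = int(round(cfg.t_final / cfg.dt))
    res = propagate_batch(
        space.energies, _interaction_matrix(space, amp), omega, width,
        centers, phases, cfg.dt, n_steps, np.asarray(C0, dtype=complex),
        coeff_stride=cfg.store_stride, norm_tol=cfg.norm_tol)
    return CoefficientTrajectory(res["times"], res["coeffs"][0],
                                 norm_drift=float(res["norm_drift"].max()))


def propagate_sse(space: ActiveSpace, seq: PulseSequence,
                  cfg: PropagationConfig, C0: np.ndarray,
                  traj_index: int = 0) -> CoefficientTrajectory:
    """One stochastic realization of the pure-dephasing SSE.

    The RNG stream is fully determined by ``(cfg.seed, traj_index)``.
    With ``dephasing_T2 = None`` (no channels) the result is bit-for-bit
    the closed-system trajectory.
    """
    if cfg.method != "sse":
        raise ValueError("cfg.method must be 'sse'")
    omega, width, amp, centers, phases = _sequence_arrays(seq)
    n_steps = int(round(cfg.t_final / cfg.dt))
    chans = dephasing_channels(space, cfg)
    rate = total_jump_rate(chans) if chans.size else 0.0
    rng = substream(cfg.seed, traj_index)
    plan = [draw_jump_plan(rng, rate, n_steps, cfg.dt)]
    res = propagate_batch(
        space.energies, _interaction_matrix(space, amp), omega, width,
        centers, phases, cfg.dt, n_steps, np.asarray(C0, dtype=complex),
        coeff_stride=cfg.store_stride,
        jump_events=plan if rate > 0 else None,
        channels=chans if rate > 0 else None,
        norm_tol=cfg.norm_tol)
    log = [(t, q) for _, t, q in res["jump_log"]]
    return CoefficientTrajectory(res["times"], res["coeffs"][0], jump_log=log,
                                 norm_drift=float(res["norm_drift"].max()))


def average_density(trajs: Sequence[CoefficientTrajectory]) -> DensityMatrixSeries:
    """Ensemble-averaged density matrix, hermitian by construction."""
    if not trajs:
        raise ValueError("no trajectories")
    t0 = trajs[0].times
    for tr in trajs[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("trajectories must share a time grid")
    rho = np.zeros((len(t0), trajs[0].coeffs.shape[1],
                    trajs[0].coeffs.shape[1]), dtype=complex)
    for tr in trajs:
        rho += np.einsum("ta,tb->tab", tr.coeffs, np.conj(tr.coeffs))
    rho /= len(trajs)
    return DensityMatrixSeries(t0.copy(), rho)


def polarization(traj: CoefficientTrajectory, space: ActiveSpace) -> np.ndarray:
    """Expectation value of the dipole, shape (n_stored, 3), real.

    ``P(t) = sum_{a,b} C_a*(t) C_b(t) mu[a, b]``; real because the
    dipole matrix is real-symmetric.
    """
    P = np.einsum("ta,abx,tb->tx", np.conj(traj.coeffs), space.dipoles,
                  traj.coeffs)
    return P.real
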