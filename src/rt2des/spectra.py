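"""From phase-matched polarization traces to 2DES maps.

The rephasing/nonrephasing components on the (tau, t') grid are double
Fourier transformed at fixed population time T,

    S_R(w1, T, w3)  = i * int dtau int dt' e^{-i w1 tau} e^{+i w3 t'} S_R(tau, T, t'),
    S_NR(w1, T, w3) = i * int dtau int dt' e^{+i w1 tau} e^{+i w3 t'} S_NR(tau, T, t'),

realized as half-axis (tau, t' >= 0) rectangle-rule FFTs with a
time-domain Gaussian window (spectral broadening) and optional zero
padding.  The real part of R + NR is the absorptive spectrum.

Axis convention: the extracted components are complex one-sided signals
(the phase-matched rotation sense is fixed by the (l, m, n) selection),
so each FFT axis covers one full unaliased period ``2*pi/dt``.  When the
physical energies exceed that period (coarse tau sampling), the axis is
unfolded by an integer number of periods chosen so the pulse carrier
frequency lies inside the displayed window -- the usual bandpass/
undersampling convention for one-sided detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .units import HARTREE_EV, au_to_fs, ev_to_hartree, fs_to_au

__all__ = [
    "SignalGrid",
    "Spectrum2D",
    "CoherenceTrace",
    "reslice_detection",
    "transform_2d",
    "make_spectrum",
    "absorptive",
    "find_peaks",
    "track_coherence",
    "fit_damped_cosine",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SignalGrid:
    """One component's complex signal on the uniform (tau, t') grid."""

    tau_axis: np.ndarray        # (n_tau,), a.u., uniform, increasing
    tprime_axis: np.ndarray     # (n_tp,), a.u., uniform, increasing
    T: float                    # population time, a.u.
    values: np.ndarray          # (n_tau, n_tp), complex
    component: str = "R"        # "R" | "NR"
    prop_dt: float | None = None  # propagation step, for dispersion-true axes

    def __post_init__(self) -> None:
        for ax in (self.tau_axis, self.tprime_axis):
            d = np.diff(ax)
            if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
                raise ValueError("axes must be strictly increasing and uniform")
        if self.values.shape != (len(self.tau_axis), len(self.tprime_axis)):
            raise ValueError("values shape does not match axes")


@dataclass
class Spectrum2D:
    """2DES maps on (omega1, omega3) grids at fixed population time."""

    omega1_ev: np.ndarray
    omega3_ev: np.ndarray
    T: float                                  # a.u.
    rephasing: np.ndarray | None = None       # complex (n1, n3)
    nonrephasing: np.ndarray | None = None
    broadening_ev: float = 0.0
    meta: dict = dc_field(default_factory=dict)
    signals: dict | None = None               # optional raw SignalGrids

    @property
    def absorptive(self) -> np.ndarray:
        if self.rephasing is None or self.nonrephasing is None:
            raise ValueError("absorptive needs both R and NR components")
        return (self.rephasing + self.nonrephasing).real

    def to_tsv(self, path, which: str = "absorptive") -> None:
        """Flat (omega1, omega3, value) export for plotting."""
        m = getattr(self, which)
        if np.iscomplexobj(m):
            m = m.real
        rows = [(w1, w3, m[i, j])
                for i, w1 in enumerate(self.omega1_ev)
                for j, w3 in enumerate(self.omega3_ev)]
        np.savetxt(path, rows, header="omega1_ev\tomega3_ev\tvalue",
                   delimiter="\t")


@dataclass
class CoherenceTrace:
    """Cross-peak amplitude versus population time (interface units: fs)."""

    pump_ev: float
    probe_ev: float
    T_axis_fs: np.ndarray
    amplitude: np.ndarray
    fit: dict | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.T_axis_fs) <= 0):
            raise ValueError("T axis must be increasing")


def reslice_detection(times: np.ndarray, trace: np.ndarray, t3: float,
                      window: float) -> tuple[np.ndarray, np.ndarray]:
    """Shift the time origin to the third-pulse center.

    Returns ``(tprime_axis, slice)`` with ``t' = t - t3`` on
    ``[0, window]``.  ``times`` must be uniform and contain ``t3`` on
    the grid (delays are snapped to the step in campaign mode); raises
    if the propagation is shorter than ``t3 + window``.
    """
    times = np.asarray(times)
    dt = times[1] - times[0]
    i0 = int(round((t3 - times[0]) / dt))
    if not np.isclose(times[0] + i0 * dt, t3, atol=dt * 1e-6):
        raise ValueError("t3 does not lie on the stored time grid")
    count = int(round(window / dt)) + 1
    if i0 < 0 or i0 + count > len(times):
        need = au_to_fs(t3 + window)
        raise ValueError(
            f"propagation too short for detection window: need t_final >= "
            f"{need:.1f} fs")
    return times[i0:i0 + count] - times[i0], trace[..., i0:i0 + count]


def _axis_unfold(n: int, dt: float, carrier_au: float) -> np.ndarray:
    """Frequency axis (a.u. angular) over one period, unfolded so the
    carrier lies inside the window."""
    period = 2.0 * np.pi / dt
    base = np.arange(n) * (period / n)
    offset = period * np.floor(carrier_au / period)
    return base + offset


def _dispersion_correct(w: np.ndarray, prop_dt: float | None) -> np.ndarray:
    """Map numerical oscillation frequencies to physical energies.

    The leapfrog propagator rotates an eigenmode of energy E at the
    numerical frequency ``arcsin(E dt)/dt``; inverting with
    ``sin(w dt)/dt`` places spectral features at the physical energies.
    The exact inverse is applied in its band of validity
    (``w dt <= 1.2``) and continued linearly beyond, keeping the axis
    monotonic; signal content always lies far below that boundary.
    """
    if prop_dt is None:
        return w
    x = w * prop_dt
    cut = 1.2
    out = np.where(x <= cut, np.sin(np.minimum(x, cut)),
                   np.sin(cut) + np.cos(cut) * (x - cut))
    return out / prop_dt


def transform_2d(grid: SignalGrid, which: str | None = None,
                 broadening_ev: float = 0.05, zero_pad: int = 2,
                 carrier_ev: float | None = None) -> Spectrum2D:
    """Double Fourier transform of one signal component.

    ``broadening_ev`` is the FWHM (eV) of the Gaussian applied in the
    frequency domain, implemented as a time-domain Gaussian window on
    both axes; ``zero_pad`` multiplies each axis length.  The carrier
    (defaults to the dominant content; pass the pulse carrier for
    reproducible unfolding) selects the displayed frequency branch.
    """
    which = which or grid.component
    if which not in ("R", "NR"):
        raise ValueError("which must be 'R' or 'NR'")
    dtau = grid.tau_axis[1] - grid.tau_axis[0]
    dtp = grid.tprime_axis[1] - grid.tprime_axis[0]
    vals = grid.values
    if broadening_ev > 0:
        sig = ev_to_hartree(broadening_ev) / _FWHM
        wtau = np.exp(-0.5 * (sig * grid.tau_axis) ** 2)
        wtp = np.exp(-0.5 * (sig * grid.tprime_axis) ** 2)
        vals = vals * wtau[:, None] * wtp[None, :]
    n1 = len(grid.tau_axis) * max(1, int(zero_pad))
    n3 = len(grid.tprime_axis) * max(1, int(zero_pad))
    # t' axis: kernel e^{+i w3 t'} for both components -> inverse FFT
    s = np.fft.ifft(vals, n=n3, axis=1) * n3
    if which == "R":
        s = np.fft.fft(s, n=n1, axis=0)          # e^{-i w1 tau}
    else:
        s = np.fft.ifft(s, n=n1, axis=0) * n1    # e^{+i w1 tau}
    s = 1j * dtau * dtp * s
    if carrier_ev is None:
        carrier_au = 0.0
    else:
        carrier_au = ev_to_hartree(carrier_ev)
    w1 = _dispersion_correct(_axis_unfold(n1, dtau, carrier_au),
                             grid.prop_dt) * HARTREE_EV
    w3 = _dispersion_correct(_axis_unfold(n3, dtp, carrier_au),
                             grid.prop_dt) * HARTREE_EV
    spec = Spectrum2D(w1, w3, grid.T, broadening_ev=broadening_ev,
                      meta={"zero_pad": zero_pad, "carrier_ev": carrier_ev})
    if which == "R":
        spec.rephasing = s
    else:
        spec.nonrephasing = s
    return spec


def make_spectrum(grid_R: SignalGrid, grid_NR: SignalGrid,
                  broadening_ev: float = 0.05, zero_pad: int = 2,
                  carrier_ev: float | None = None) -> Spectrum2D:
    """Transform both components onto one common Spectrum2D."""
    sR = transform_2d(grid_R, "R", broadening_ev, zero_pad, carrier_ev)
    sNR = transform_2d(grid_NR, "NR", broadening_ev, zero_pad, carrier_ev)
    if sR.omega1_ev.shape != sNR.omega1_ev.shape or \
            not np.allclose(sR.omega1_ev, sNR.omega1_ev):
        raise ValueError("component grids disagree")
    sR.nonrephasing = sNR.nonrephasing
    return sR


def crop_spectrum(spec: Spectrum2D, omega1_range: tuple[float, float],
                  omega3_range: tuple[float, float]) -> Spectrum2D:
    """Restrict a spectrum to a display window (eV on both axes).

    The full FFT output spans one sampling period per axis and includes
    the counter-rotating alias branch far from the carrier; maps are
    conventionally displayed on the physical band covered by the pulse
    spectrum.
    """
    s1 = (spec.omega1_ev >= omega1_range[0]) & (spec.omega1_ev <= omega1_range[1])
    s3 = (spec.omega3_ev >= omega3_range[0]) & (spec.omega3_ev <= omega3_range[1])
    if not (s1.any() and s3.any()):
        raise ValueError("display window does not intersect the grid")
    out = Spectrum2D(spec.omega1_ev[s1], spec.omega3_ev[s3], spec.T,
                     broadening_ev=spec.broadening_ev, meta=dict(spec.meta))
    if spec.rephasing is not None:
        out.rephasing = spec.rephasing[np.ix_(s1, s3)]
    if spec.nonrephasing is not None:
        out.nonrephasing = spec.nonrephasing[np.ix_(s1, s3)]
    return out


def absorptive(spec_R: np.ndarray, spec_NR: np.ndarray) -> np.ndarray:
    """Real part of the sum of rephasing and nonrephasing maps."""
    if np.shape(spec_R) != np.shape(spec_NR):
        raise ValueError("grid mismatch between R and NR maps")
    return (np.asarray(spec_R) + np.asarray(spec_NR)).real


def find_peaks(spec: Spectrum2D, threshold: float = 0.1,
               min_separation_ev: float = 0.05,
               which: str = "absorptive") -> list[tuple[float, float, float, int]]:
    """Local extrema of a map above ``threshold * max|map|``.

    Returns ``(omega1_ev, omega3_ev, value, sign)`` tuples ordered by
    decreasing |value|; positive peaks are bleach/stimulated-emission
    type, negative ones excited-state absorption.
    """
    m = getattr(spec, which)
    if np.iscomplexobj(m):
        m = m.real
    vmax = np.abs(m).max()
    if vmax == 0:
        return []
    d1 = spec.omega1_ev[1] - spec.omega1_ev[0]
    d3 = spec.omega3_ev[1] - spec.omega3_ev[0]
    size = (max(1, int(round(min_separation_ev / d1)) * 2 + 1),
            max(1, int(round(min_separation_ev / d3)) * 2 + 1))
    peaks = []
    for sign, mm in ((1, m), (-1, -m)):
        loc = (mm == ndimage.maximum_filter(mm, size=size, mode="nearest"))
        loc &= mm >= threshold * vmax
        for i, j in zip(*np.nonzero(loc)):
            peaks.append((float(spec.omega1_ev[i]), float(spec.omega3_ev[j]),
                          float(m[i, j]), sign))
    peaks.sort(key=lambda p: -abs(p[2]))
    # a flat ridge can satisfy both filters; drop duplicates
    seen, out = set(), []
    for p in peaks:
        if (p[0], p[1]) not in seen:
            seen.add((p[0], p[1]))
            out.append(p)
    return out


def _nearest_index(axis: np.ndarray, value: float) -> int:
    i = int(np.argmin(np.abs(axis - value)))
    if abs(axis[i] - value) > 1.5 * abs(axis[1] - axis[0]):
        raise ValueError(f"coordinate {value} eV outside the map grid")
    return i


def track_coherence(specs: list[Spectrum2D], pump_ev: float, probe_ev: float,
                    which: str = "absorptive",
                    magnitude: bool = False) -> CoherenceTrace:
    """Sample a fixed (pump, probe) map point across population times.

    Uses the nearest grid point of each (common-grid) map; by default
    the signed absorptive value, or |value| with ``magnitude=True``.
    """
    if not specs:
        raise ValueError("no spectra")
    ref = specs[0]
    i = _nearest_index(ref.omega1_ev, pump_ev)
    j = _nearest_index(ref.omega3_ev, probe_ev)
    amps, times = [], []
    for sp in specs:
        if sp.omega1_ev.shape != ref.omega1_ev.shape or \
                not np.allclose(sp.omega1_ev, ref.omega1_ev):
            raise ValueError("maps must share a common grid")
        m = getattr(sp, which)
        if np.iscomplexobj(m):
            m = m.real
        v = float(m[i, j])
        amps.append(abs(v) if magnitude else v)
        times.append(au_to_fs(sp.T))
    order = np.argsort(times)
    return CoherenceTrace(pump_ev, probe_ev,
                          np.asarray(times)[order], np.asarray(amps)[order])


def fit_damped_cosine(trace: CoherenceTrace, damped: bool = True) -> dict:
    """Fit ``A cos(Omega t + phi) exp(-t / tau_d) + c`` to the trace.

    The undamped variant fixes ``tau_d = inf``.  Nonlinear least squares
    with multi-start initialization: Omega is seeded from the dominant
    discrete-Fourier component of the detrended trace, the phase and
    decay time from a small start grid.  Returns the parameters (fs
    units: Omega in rad/fs, tau_d in fs) with asymptotic standard
    errors, and attaches the result to ``trace.fit``.
    """
    t = np.asarray(trace.T_axis_fs, dtype=float)
    y = np.asarray(trace.amplitude, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit")
    t0 = t - t[0]
    c0 = y.mean()
    span = t0[-1] if t0[-1] > 0 else 1.0
    # dominant frequency of the detrended trace (uniform-grid estimate)
    dt_mean = np.mean(np.diff(t0))
    yf = np.fft.rfft(y - c0, n=8 * len(y))
    fgrid = 2 * np.pi * np.fft.rfftfreq(8 * len(y), dt_mean)
    om0 = float(fgrid[np.argmax(np.abs(yf[1:])) + 1])
    a0 = max(np.sqrt(2.0) * np.std(y), 1e-30)

    def model(p, t):
        if damped:
            A, om, ph, tau, c = p
            # clip so sign-crossing tau excursions of the optimizer
            # cannot overflow
            return (A * np.cos(om * t + ph)
                    * np.exp(np.clip(-t / tau, -700.0, 50.0)) + c)
        A, om, ph, c = p
        return A * np.cos(om * t + ph) + c

    def resid(p):
        return model(p, t0) - y

    def jac(p):
        if damped:
            A, om, ph, tau, c = p
            e = np.exp(np.clip(-t0 / tau, -700.0, 50.0))
            cs, sn = np.cos(om * t0 + ph), np.sin(om * t0 + ph)
            return np.column_stack([
                cs * e, -A * t0 * sn * e, -A * sn * e,
                A * cs * e * t0 / tau**2, np.ones_like(t0)])
        A, om, ph, c = p
        cs, sn = np.cos(om * t0 + ph), np.sin(om * t0 + ph)
        return np.column_stack([cs, -A * t0 * sn, -A * sn,
                                np.ones_like(t0)])

    best = None
    # signed amplitude makes pi-shifted phase starts redundant
    phases = (0.0, 0.5 * np.pi)
    taus = (span / 3.0, span, 3.0 * span) if damped else (None,)
    omegas = (om0, 0.5 * om0, 2.0 * om0) if om0 > 0 else (2 * np.pi / span,)
    floor = 1e-12 * max(float(np.sum((y - c0) ** 2)), 1e-300)
    for om_s in omegas:
        for ph in phases:
            for tau_s in taus:
                p0 = ([a0, om_s, ph, tau_s, c0] if damped
                      else [a0, om_s, ph, c0])
                try:
                    sol = optimize.least_squares(resid, p0, jac=jac,
                                                 method="lm", max_nfev=2000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is not None and best.cost <= floor:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("damped-cosine fit failed to converge from all "
                           f"starts (n={len(t)}, om0={om0:.3g} rad/fs)")
    p = best.x
    dof = max(len(t) - len(p), 1)
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * 2 * best.cost / dof
        err = np.sqrt(np.abs(np.diag(cov)))
    except np.linalg.LinAlgError:
        err = np.full(len(p), np.nan)
    if damped:
        keys = ("amplitude", "omega_rad_fs", "phase", "decay_fs", "offset")
    else:
        keys = ("amplitude", "omega_rad_fs", "phase", "offset")
    fit = {k: float(v) for k, v in zip(keys, p)}
    fit.update({k + "_err": float(e) for k, e in zip(keys, err)})
    if not damped:
        fit["decay_fs"] = np.inf
    # canonicalize: positive amplitude and frequency
    if fit["amplitude"] < 0:
        fit["amplitude"] = -fit["amplitude"]
        fit["phase"] += np.pi
    if fit["omega_rad_fs"] < 0:
        fit["omega_rad_fs"] = -fit["omega_rad_fs"]
        fit["phase"] = -fit["phase"]
    fit["phase"] = float(np.mod(fit["phase"] + np.pi, 2 * np.pi) - np.pi)
    fit["cost"] = float(best.cost)
    trace.fit = fit
    return fit
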