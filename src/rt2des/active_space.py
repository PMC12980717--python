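"""Electronic active space: energies and transition dipoles of a finite
set of field-free eigenstates.

The active space is the propagation basis: the ground state (index 0,
energy fixed to zero) plus excited states with excitation energies
``E_lambda`` and the full transition-dipole matrix
``<lambda'| mu_vec |lambda>`` (n_states x n_states x 3, atomic units).
Quantities typically come from an excited-state electronic-structure
calculation; this module only validates, reads, writes and synthesizes
them -- it never computes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .units import HARTREE_EV

__all__ = [
    "ActiveSpace",
    "ActiveSpaceError",
    "load_active_space",
    "save_active_space",
    "make_fixture",
    "FIXTURE_NAMES",
]

#: Maximum allowed asymmetry |mu[a,b] - mu[b,a]| for real eigenstates.
DIPOLE_SYMMETRY_TOL = 1e-10


class ActiveSpaceError(ValueError):
    """Raised when an active space violates its invariants or schema."""


@dataclass(frozen=True)
class ActiveSpace:
    """Validated electronic active space in atomic units.

    Parameters
    ----------
    energies
        Excitation energies in hartree, ``energies[0] == 0``, sorted
        non-decreasing.
    dipoles
        Transition-dipole matrix, shape ``(n, n, 3)``, symmetric under
        state exchange.  Diagonal (permanent) dipoles are allowed.
    labels
        Optional per-state names such as ``"S1"``.
    """

    energies: np.ndarray
    dipoles: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.dipoles, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "dipoles", mu)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.energies.shape[0]

    def validate(self) -> None:
        e, mu = self.energies, self.dipoles
        if e.ndim != 1 or e.shape[0] < 2:
            raise ActiveSpaceError("active space needs at least 2 states")
        n = e.shape[0]
        if mu.shape != (n, n, 3):
            raise ActiveSpaceError(
                f"dipole matrix shape {mu.shape} incompatible with {n} states"
            )
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(mu))):
            raise ActiveSpaceError("non-finite energy or dipole entry")
        if e[0] != 0.0:
            raise ActiveSpaceError("ground-state energy must be exactly 0")
        if np.any(e < 0):
            raise ActiveSpaceError("negative excitation energy")
        if np.any(np.diff(e) < 0):
            raise ActiveSpaceError("energies must be sorted non-decreasing")
        asym = np.abs(mu - mu.transpose(1, 0, 2))
        if asym.max() > DIPOLE_SYMMETRY_TOL:
            a, b, _ = np.unravel_index(np.argmax(asym), asym.shape)
            raise ActiveSpaceError(
                f"dipole matrix not symmetric: states ({a},{b}), "
                f"|mu[a,b]-mu[b,a]| = {asym.max():.3e}"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ActiveSpaceError("labels length must equal n_states")

    def dipole_along(self, axis: np.ndarray) -> np.ndarray:
        """Project the dipole matrix on a (unit) lab axis -> (n, n)."""
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        return np.tensordot(self.dipoles, ax, axes=([2], [0]))

    def energies_ev(self) -> np.ndarray:
        return self.energies * HARTREE_EV


def _from_raw(energies, dipoles, energy_unit: str, labels=None) -> ActiveSpace:
    e = np.asarray(energies, dtype=float)
    if energy_unit == "eV":
        e = e / HARTREE_EV
    elif energy_unit != "hartree":
        raise ActiveSpaceError(f"unknown energy unit {energy_unit!r}")
    return ActiveSpace(e, np.asarray(dipoles, dtype=float),
                       tuple(labels) if labels else None)


def load_active_space(
    path: str | Path,
    unit_hint: str | None = None,
    dipole_path: str | Path | None = None,
) -> ActiveSpace:
    """Load and validate an active space.

    Two formats are accepted:

    * a JSON object with keys ``n_states``, ``energy_unit`` ("eV" or
      "hartree"), ``energies``, ``dipoles`` (nested ``[n][n][3]``, a.u.)
      and optional ``labels``;
    * a columnar pair for interoperability with quantum-chemistry
      exports: ``path`` is a one-line-per-state energies file (unit from
      ``unit_hint``, default eV) and ``dipole_path`` a file with one
      ``a b mux muy muz`` line per state pair (symmetric completion is
      *not* performed: both orders, or only one with the other implied
      by symmetry, may be listed but conflicts are errors).

    Validation failures raise :class:`ActiveSpaceError`; nothing is
    silently fixed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for key in ("n_states", "energy_unit", "energies", "dipoles"):
            if key not in data:
                raise ActiveSpaceError(f"missing field {key!r} in {path}")
        space = _from_raw(data["energies"], data["dipoles"],
                          unit_hint or data["energy_unit"],
                          data.get("labels"))
        if space.n_states != data["n_states"]:
            raise ActiveSpaceError("n_states field disagrees with energies")
        return space
    # columnar text
    energies = np.loadtxt(path, ndmin=1)
    n = energies.shape[0]
    if dipole_path is None:
        dipole_path = path.with_suffix(".dipoles")
    rows = np.loadtxt(dipole_path, ndmin=2)
    mu = np.full((n, n, 3), np.nan)
    for a, b, x, y, z in rows:
        a, b = int(a), int(b)
        vec = np.array([x, y, z])
        for i, j in ((a, b), (b, a)):
            if np.all(np.isfinite(mu[i, j])) and not np.allclose(mu[i, j], vec):
                raise ActiveSpaceError(f"conflicting dipole entries for ({i},{j})")
            mu[i, j] = vec
    mu[np.isnan(mu)] = 0.0
    return _from_raw(energies, mu, unit_hint or "eV")


def save_active_space(space: ActiveSpace, path: str | Path,
                      energy_unit: str = "hartree") -> None:
    """Write an active space as the documented JSON schema."""
    e = space.energies
    if energy_unit == "eV":
        e = e * HARTREE_EV
    elif energy_unit != "hartree":
        raise ActiveSpaceError(f"unknown energy unit {energy_unit!r}")
    data = {
        "n_states": space.n_states,
        "energy_unit": energy_unit,
        "energies": e.tolist(),
        "dipoles": space.dipoles.tolist(),
    }
    if space.labels is not None:
        data["labels"] = list(space.labels)
    Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("benzene_like", "chlorophyll_like", "dimer_like")

# Excitation energies (eV) of the emulated systems.  Dipole magnitudes are a
# package choice (default 1.0 a.u. along z); peak positions in the weak-field
# regime depend only on the energies.
_BENZENE_BRIGHT_EV = 5.61
_CHL_S1_EV = 2.31
_CHL_ESA_GAP_EV = 2.27          # S1 -> upper-state transition energy
_DIMER_EV = (4.96, 5.76, 5.93, 6.05, 6.18)


def make_fixture(name: str, dipole_scale: float = 1.0) -> ActiveSpace:
    """Build one of the three bundled synthetic model systems.

    benzene_like
        Ground state plus a single bright state at 5.61 eV.
    chlorophyll_like
        Ground, S1 at 2.31 eV and an upper state at 2.31 + 2.27 eV that
        is reachable only from S1 (zero ground-state dipole): the
        minimal system showing excited-state absorption.
    dimer_like
        Ground plus five excited states at 4.96, 5.76, 5.93, 6.05 and
        6.18 eV, all dipole-coupled to the ground state.

    All transition dipoles have magnitude ``dipole_scale`` (a.u.) along
    the z axis; permanent dipoles are zero.
    """
    z = np.array([0.0, 0.0, 1.0]) * dipole_scale
    if name == "benzene_like":
        ev = [0.0, _BENZENE_BRIGHT_EV]
        mu = np.zeros((2, 2, 3))
        mu[0, 1] = mu[1, 0] = z
        labels = ("S0", "S1")
    elif name == "chlorophyll_like":
        ev = [0.0, _CHL_S1_EV, _CHL_S1_EV + _CHL_ESA_GAP_EV]
        mu = np.zeros((3, 3, 3))
        mu[0, 1] = mu[1, 0] = z
        mu[1, 2] = mu[2, 1] = z        # ESA channel from S1
        labels = ("S0", "S1", "Shigh")
    elif name == "dimer_like":
        ev = [0.0, *_DIMER_EV]
        n = len(ev)
        mu = np.zeros((n, n, 3))
        for k in range(1, n):
            mu[0, k] = mu[k, 0] = z
        labels = ("S0",) + tuple(f"E{k}" for k in range(1, n))
    else:
        raise ActiveSpaceError(f"unknown fixture {name!r}")
    return _from_raw(ev, mu, "eV", labels)
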