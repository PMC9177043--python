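"""Metadynamics bias on the periodic path-progress axis, tube potential and
harmonic/steered restraints.

The bias is plain (non-well-tempered) metadynamics: Gaussians of fixed width
(default 0.1 path-progress units) and fixed height (default 0.05 kcal/mol)
deposited at a fixed pace (default every 1 ps) on the periodic s axis
(period 2, s in [-1, +1]).  All standard walkers of one path share a single
hill list; attractor walkers never deposit.  A *tube* potential -- an upper
harmonic wall at z = 0 on the component perpendicular to the path, default
force constant 50 kcal/mol per squared path unit -- keeps every walker near
its path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RoleError

__all__ = [
    "Hill",
    "HillList",
    "TubePotential",
    "RestraintSchedule",
    "Walker",
    "WalkerEnsemble",
    "bias_energy_force",
    "deposit_hill",
    "restraint_energy_force",
    "write_hills",
    "read_hills",
    "BiasGrid",
]

S_PERIOD = 2.0


def wrap_s(delta):
    """Minimum-image difference on the periodic s axis (period 2)."""
    return (np.asarray(delta) + 1.0) % S_PERIOD - 1.0


@dataclass(frozen=True)
class Hill:
    """One Gaussian bias potential on the s axis."""

    center: float
    width: float = 0.1
    height: float = 0.05
    deposit_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError("hill width must be > 0")
        if not self.height > 0:
            raise ParameterError("hill height must be > 0")


class HillList:
    """Append-only list of hills shared by all standard walkers of one path.

    Stored as growing flat arrays so that evaluating the bias over thousands
    of hills stays vectorized.
    """

    def __init__(self, hills=()) -> None:
        self.centers: list[float] = []
        self.widths: list[float] = []
        self.heights: list[float] = []
        self.times: list[float] = []
        for h in hills:
            self.append(h)

    def append(self, hill: Hill) -> None:
        self.centers.append(float(hill.center))
        self.widths.append(float(hill.width))
        self.heights.append(float(hill.height))
        self.times.append(float(hill.deposit_time))

    def __len__(self) -> int:
        return len(self.centers)

    def __iter__(self):
        for c, w, h, t in zip(self.centers, self.widths, self.heights, self.times):
            yield Hill(c, w, h, t)

    def arrays(self):
        return (
            np.asarray(self.centers),
            np.asarray(self.widths),
            np.asarray(self.heights),
            np.asarray(self.times),
        )


def bias_energy_force(s, hills: HillList, t_max: float | None = None):
    """Total bias energy and its s-derivative at progress ``s``.

    E(s) = sum_i h_i exp(-d_i^2 / (2 w_i^2)) with d_i the period-2
    minimum-image distance to hill i; the second return value is dE/ds.
    An empty list gives (0, 0).  If ``t_max`` is given only hills deposited at
    or before that time contribute.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if len(hills) == 0:
        e = np.zeros_like(s_arr)
        return (float(e[0]), 0.0) if np.isscalar(s) or s_arr.size == 1 else (e, e)
    c, w, h, times = hills.arrays()
    if t_max is not None:
        keep = times <= t_max
        c, w, h = c[keep], w[keep], h[keep]
    d = wrap_s(s_arr[:, None] - c[None, :])
    g = h[None, :] * np.exp(-0.5 * (d / w[None, :]) ** 2)
    energy = g.sum(axis=1)
    dEds = -(g * d / w[None, :] ** 2).sum(axis=1)
    if np.isscalar(s) or np.asarray(s).ndim == 0:
        return float(energy[0]), float(dEds[0])
    return energy, dEds


class BiasGrid:
    """Incrementally maintained bias energy/derivative on a fixed s grid.

    Used by the engine so the per-step bias force costs O(grid) interpolation
    instead of O(n_hills).  Evaluation is linear interpolation on a periodic
    grid; :func:`bias_energy_force` remains the exact reference.
    """

    def __init__(self, n_bins: int = 800) -> None:
        self.s_grid = -1.0 + S_PERIOD * np.arange(n_bins) / n_bins
        self.energy = np.zeros(n_bins)
        self.dEds = np.zeros(n_bins)
        self._n = n_bins

    def add_hill(self, hill: Hill) -> None:
        d = wrap_s(self.s_grid - hill.center)
        g = hill.height * np.exp(-0.5 * (d / hill.width) ** 2)
        self.energy += g
        self.dEds += -g * d / hill.width**2

    def evaluate(self, s):
        x = (np.asarray(s, dtype=float) + 1.0) % S_PERIOD / S_PERIOD * self._n
        i0 = np.floor(x).astype(int) % self._n
        i1 = (i0 + 1) % self._n
        f = x - np.floor(x)
        e = (1 - f) * self.energy[i0] + f * self.energy[i1]
        de = (1 - f) * self.dEds[i0] + f * self.dEds[i1]
        return e, de


@dataclass(frozen=True)
class TubePotential:
    """Upper harmonic wall at z = 0: E = 1/2 k z^2 for z > 0."""

    force_constant: float = 50.0
    wall_position: float = 0.0

    def energy_force(self, z):
        z = np.asarray(z, dtype=float)
        excess = np.maximum(z - self.wall_position, 0.0)
        e = 0.5 * self.force_constant * excess**2
        dEdz = self.force_constant * excess
        return e, dEdz


@dataclass
class RestraintSchedule:
    """Harmonic restraint on a CV, optionally with linear steering.

    ``target_cv`` names the restrained quantity ("s", "theta", or "point" for
    a full CV-space point).  With a steering window the center moves linearly
    from ``start`` to ``center`` over ``(t0, t0 + window)`` and is constant
    afterwards; without one the center is fixed at ``center``.
    ``periodic`` gives the period for period-aware differences (2 for s).
    """

    target_cv: str
    force_constant: float
    center: object
    start: object | None = None
    window: float | None = None
    t0: float = 0.0
    periodic: float | None = None

    def __post_init__(self) -> None:
        if self.window is not None and not self.window > 0:
            raise ParameterError("steering window must be > 0")
        if self.window is not None and self.start is None:
            raise ParameterError("steering requires a start value")

    def center_at(self, t: float):
        if self.window is None:
            return self.center
        lam = np.clip((t - self.t0) / self.window, 0.0, 1.0)
        c0 = np.asarray(self.start, dtype=float)
        c1 = np.asarray(self.center, dtype=float)
        if self.periodic is not None:
            half = self.periodic / 2.0
            d = (c1 - c0 + half) % self.periodic - half
            c = c0 + lam * d
        else:
            c = c0 + lam * (c1 - c0)
        return float(c) if c.ndim == 0 else c


def restraint_energy_force(value, schedule: RestraintSchedule, t: float = 0.0):
    """Energy 1/2 k (value - center(t))^2 and derivative dE/dvalue.

    For periodic CVs the difference is minimum-image.  For "point" restraints
    ``value`` is a vector and the returned force is the gradient vector.
    """
    c = schedule.center_at(t)
    v = np.asarray(value, dtype=float)
    d = v - np.asarray(c, dtype=float)
    if schedule.periodic is not None:
        half = schedule.periodic / 2.0
        d = (d + half) % schedule.periodic - half
    k = schedule.force_constant
    energy = 0.5 * k * float(np.sum(d * d))
    grad = k * d
    if v.ndim == 0:
        return energy, float(grad)
    return energy, grad


@dataclass
class Walker:
    """One replica: role, current CV position and attached restraints."""

    role: str
    position: np.ndarray
    restraints: list = field(default_factory=list)
    index: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("standard", "attractor"):
            raise ParameterError(f"unknown walker role {self.role!r}")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class WalkerEnsemble:
    """All walkers of one path (default 9 standard + 3 attractors).

    Only standard walkers deposit hills; attractors are excluded from the
    free-energy calculation but do guide path updates.  All walkers feel the
    tube potential.
    """

    walkers: list

    @property
    def standard(self):
        return [w for w in self.walkers if w.role == "standard"]

    @property
    def attractors(self):
        return [w for w in self.walkers if w.role == "attractor"]


def deposit_hill(
    walker: Walker,
    s: float,
    hills: HillList,
    time: float,
    width: float = 0.1,
    height: float = 0.05,
) -> HillList:
    """Append a hill at the walker's current progress to the shared list.

    Attractor walkers are rejected: they do not take part in the free-energy
    calculation.  When several standard walkers deposit in the same pace
    window, hills are appended in walker-index order (the caller iterates
    walkers in order), so every walker sees the full shared list before its
    next step.
    """
    if walker.role != "standard":
        raise RoleError("only standard walkers deposit hills")
    hills.append(Hill(float(wrap_s(s)), width, height, time))
    return hills


# ---------------------------------------------------------------------------
# HILLS files


def write_hills(hills: HillList, filename) -> None:
    """Plain-text hill log: time, center, width, height per line."""
    with open(filename, "w") as fh:
        fh.write("# time center width height\n")
        for h in hills:
            fh.write(
                f"{h.deposit_time:.17g} {h.center:.17g} {h.width:.17g} {h.height:.17g}\n"
            )


def read_hills(filename) -> HillList:
    """Parse a hill log written by :func:`write_hills` (lossless)."""
    out = HillList()
    with open(filename) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, c, w, h = (float(v) for v in line.split()[:4])
            out.append(Hill(c, w, h, t))
    return out
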