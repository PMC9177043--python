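"""Analytic model potentials for the Langevin surrogate engine.

The central landscape is the *rotor-flip* potential on (chi', theta): a
periodic rotor in the base-rolling angle chi' with two minima (the WCF and HG
states), whose rotation barrier is lowered inside a Gaussian gate around the
flipped-open channel at theta = -pi/2.  This reproduces, at desk scale, the
two-channel inside/outside topology of the Watson-Crick-Franklin to Hoogsteen
transition: rolling can proceed "inside" the helix (theta near 0, high
barrier) or "outside" after flipping toward the major groove (theta near
-pi/2, lower barrier), in either the 3' (chi' through 0) or the 5' (chi'
through +/-pi) direction, with barrier ordering

    outside-3' < inside-3' < outside-5' < inside-5'.

All potentials expose ``energy(x)`` and ``gradient(x)`` on (n, d) arrays,
finite and C1 everywhere, periodic in chi' with period 2 pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnalyticPotential",
    "RotorFlipParams",
    "RotorFlipPotential",
    "DoubleChannel2D",
    "HarmonicWell",
    "FlatPotential",
    "DoubleWell1D",
    "KT_300K",
]

KT_300K = 0.596  # kcal/mol at 300 K


class AnalyticPotential:
    """Base class: analytic energy and gradient over CV coordinates."""

    ndim: int = 2
    periodic_axes: tuple[int, ...] = ()

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class RotorFlipParams:
    """Parameters of the rotor-flip landscape.

    chi_wcf, chi_hg : rad
        Rolling-angle positions of the two stable states (defaults +1.5 and
        -1.5 rad, the characteristic values of WCF and HG base pairing).
    b_in_3p, b_in_5p : kcal/mol
        Inside (closed-helix) rotation barrier scales in the 3' and 5'
        directions; the 5' scale is larger.
    b_out : kcal/mol
        Outside (flipped-open) rotation barrier scale; the closed form applies
        a fixed 5'/3' anisotropy on top of it so that the barrier is larger on
        the 5' half for the outside channel as well.
    theta_out : rad
        Opening angle of the outside channel (default -pi/2: major groove).
    sigma_theta : rad
        Width of the Gaussian gate that lowers the rotation barrier near
        theta_out.
    k_open : kcal/(mol rad^2)
        Harmonic stiffness of base opening.
    delta_f_hg : kcal/mol
        Free-energy offset of the HG basin above WCF (> 0: WCF preferred).
    """

    chi_wcf: float = 1.5
    chi_hg: float = -1.5
    b_in_3p: float = 8.5
    b_in_5p: float = 7.6
    b_out: float = 4.6
    theta_out: float = -np.pi / 2
    sigma_theta: float = 0.45
    k_open: float = 1.2
    delta_f_hg: float = 1.0
    out_anisotropy: float = 0.15  # extra 5' scaling of the outside barrier
    wall_power: float = 1.5  # exponent on the rotor factor (basin/wall shape)


class RotorFlipPotential(AnalyticPotential):
    """V(chi', theta) = B(chi', theta) r(chi') + k_open theta^2 + tilt(chi').

    r(chi') is [1 - cos(chi' - chi_wcf)] [1 - cos(chi' - chi_hg)] raised to
    ``wall_power`` and normalized to 1 at the 3' mid-rotation (chi' = 0 for
    the default states): it vanishes super-quadratically at both stable
    states (wide basins), keeps barrier walls gentle enough that the profile
    along an adapted path is resolvable at the reference hill width, and the
    inside barrier scales read directly as approximate channel barrier
    heights.  B interpolates between the inside barrier scale
    (direction-dependent, larger on the 5' half) and the outside scale through
    a Gaussian gate in theta centered at theta_out.  The tilt is a smoothstep
    in the rolling progress raising the HG basin by delta_f_hg with vanishing
    curvature at the WCF minimum, so that the basin free-energy offset equals
    delta_f_hg to high accuracy.
    """

    ndim = 2
    periodic_axes = (0,)

    def __init__(self, params: RotorFlipParams | None = None) -> None:
        self.params = params or RotorFlipParams()
        p = self.params
        mid_3p = 0.5 * (p.chi_wcf + p.chi_hg)  # 3' mid-rotation angle
        self._rnorm = ((1.0 - np.cos(mid_3p - p.chi_wcf))
                       * (1.0 - np.cos(mid_3p - p.chi_hg))) ** p.wall_power

    # -- pieces -----------------------------------------------------------
    def _r_lin(self, chi):
        p = self.params
        return (1.0 - np.cos(chi - p.chi_wcf)) * (1.0 - np.cos(chi - p.chi_hg))

    def _r_lin_prime(self, chi):
        p = self.params
        a, b = chi - p.chi_wcf, chi - p.chi_hg
        return np.sin(a) * (1.0 - np.cos(b)) + (1.0 - np.cos(a)) * np.sin(b)

    def _r(self, chi):
        return self._r_lin(chi) ** self.params.wall_power / self._rnorm

    def _r_prime(self, chi):
        pw = self.params.wall_power
        return pw * self._r_lin(chi) ** (pw - 1.0) * self._r_lin_prime(chi) / self._rnorm

    def _direction(self, chi):
        # 0 on the 3' half (chi' near 0), 1 on the 5' half (chi' near +/-pi)
        return 0.5 * (1.0 - np.cos(chi))

    def _gate(self, theta):
        p = self.params
        return np.exp(-0.5 * ((theta - p.theta_out) / p.sigma_theta) ** 2)

    def _barrier_scales(self, chi):
        p = self.params
        dirw = self._direction(chi)
        b_in = p.b_in_3p + (p.b_in_5p - p.b_in_3p) * dirw
        b_out = p.b_out * (1.0 + p.out_anisotropy * dirw)
        return b_in, b_out

    def _tilt(self, chi):
        p = self.params
        u = 0.5 * (1.0 - np.cos(chi - p.chi_wcf))
        h = u * u * (3.0 - 2.0 * u)
        return p.delta_f_hg * h

    def _tilt_prime(self, chi):
        p = self.params
        u = 0.5 * (1.0 - np.cos(chi - p.chi_wcf))
        du = 0.5 * np.sin(chi - p.chi_wcf)
        return p.delta_f_hg * 6.0 * u * (1.0 - u) * du

    # -- interface --------------------------------------------------------
    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        chi, theta = x[..., 0], x[..., 1]
        p = self.params
        b_in, b_out = self._barrier_scales(chi)
        g = self._gate(theta)
        barrier = b_in * (1.0 - g) + b_out * g
        v = barrier * self._r(chi) + p.k_open * theta**2 + self._tilt(chi)
        return v if v.size > 1 else float(v[0])

    def gradient(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        chi, theta = x[..., 0], x[..., 1]
        p = self.params
        dirw = self._direction(chi)
        ddir = 0.5 * np.sin(chi)
        b_in = p.b_in_3p + (p.b_in_5p - p.b_in_3p) * dirw
        b_out = p.b_out * (1.0 + p.out_anisotropy * dirw)
        db_in = (p.b_in_5p - p.b_in_3p) * ddir
        db_out = p.b_out * p.out_anisotropy * ddir
        g = self._gate(theta)
        dg = -g * (theta - p.theta_out) / p.sigma_theta**2
        barrier = b_in * (1.0 - g) + b_out * g
        dbarrier_dchi = db_in * (1.0 - g) + db_out * g
        dbarrier_dtheta = (b_out - b_in) * dg
        r = self._r(chi)
        dchi = dbarrier_dchi * r + barrier * self._r_prime(chi) + self._tilt_prime(chi)
        dtheta = dbarrier_dtheta * r + 2.0 * p.k_open * theta
        grad = np.stack([dchi, dtheta], axis=-1)
        return grad if grad.shape[0] > 1 else grad[0]


class DoubleChannel2D(AnalyticPotential):
    """Generic two-channel landscape on the (x, y) plane.

    V = a (x^2 - 1)^2 + c (y^2 - (1 - x^2))^2

    has two minima at (+/-1, 0) connected by two symmetric channels that hug
    the unit circle through (0, +1) and (0, -1), with saddle value ~a and a
    ridge of height a + c between the channels at the origin.  Used for
    minimum free-energy path convergence checks against a zero-temperature
    string oracle.
    """

    ndim = 2
    periodic_axes = ()

    def __init__(self, a: float = 1.0, c: float = 2.0) -> None:
        self.a = a
        self.c = c

    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xx, yy = x[..., 0], x[..., 1]
        q = yy**2 - (1.0 - xx**2)
        v = self.a * (xx**2 - 1.0) ** 2 + self.c * q**2
        return v if v.size > 1 else float(v[0])

    def gradient(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xx, yy = x[..., 0], x[..., 1]
        q = yy**2 - (1.0 - xx**2)
        gx = 4.0 * self.a * xx * (xx**2 - 1.0) + 4.0 * self.c * q * xx
        gy = 4.0 * self.c * q * yy
        grad = np.stack([gx, gy], axis=-1)
        return grad if grad.shape[0] > 1 else grad[0]


class HarmonicWell(AnalyticPotential):
    """Isotropic harmonic well 1/2 k |x - x0|^2 in d dimensions."""

    def __init__(self, k: float = 1.0, center=None, ndim: int = 1) -> None:
        self.k = k
        self.ndim = ndim
        self.center = np.zeros(ndim) if center is None else np.asarray(center, dtype=float)

    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        v = 0.5 * self.k * np.sum((x - self.center) ** 2, axis=-1)
        return v if v.size > 1 else float(v[0])

    def gradient(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        grad = self.k * (x - self.center)
        return grad if grad.shape[0] > 1 else grad[0]


class FlatPotential(AnalyticPotential):
    """Zero energy everywhere (free diffusion)."""

    def __init__(self, ndim: int = 2, periodic_axes: tuple[int, ...] = (0,)) -> None:
        self.ndim = ndim
        self.periodic_axes = periodic_axes

    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        v = np.zeros(x.shape[0])
        return v if v.size > 1 else 0.0

    def gradient(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        grad = np.zeros_like(x)
        return grad if grad.shape[0] > 1 else grad[0]


class DoubleWell1D(AnalyticPotential):
    """Quartic double well a (x^2 - 1)^2 on the first axis, flat elsewhere."""

    def __init__(self, a: float = 1.0, ndim: int = 2) -> None:
        self.a = a
        self.ndim = ndim

    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        v = self.a * (x[..., 0] ** 2 - 1.0) ** 2
        return v if v.size > 1 else float(v[0])

    def gradient(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        grad = np.zeros_like(x)
        grad[..., 0] = 4.0 * self.a * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        return grad if grad.shape[0] > 1 else grad[0]
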