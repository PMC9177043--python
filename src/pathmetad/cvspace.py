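"""Collective-variable spaces.

A CV space is an ordered list of named axes. Each axis is either linear or
periodic with a stated period. Paths for the base-rolling problem live in the
embedded space [cos(chi'), sin(chi'), theta]: the periodicity of the rolling
angle chi' is absorbed by the (cos, sin) embedding, so the embedded space
itself is purely linear and plain Euclidean distances apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DimensionalError(ValueError):
    """A point does not match the dimensionality of its CV space."""


@dataclass(frozen=True)
class Axis:
    """One named CV axis.

    Parameters
    ----------
    name : str
        Axis label (e.g. ``"cos_chi"``, ``"theta"``).
    kind : str
        ``"linear"`` or ``"periodic"``.
    period : float or None
        Period for periodic axes (required), ``None`` for linear axes.
    units : str
        ``"rad"`` or ``"dimensionless"``.
    """

    name: str
    kind: str = "linear"
    period: float | None = None
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "periodic"):
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if self.kind == "periodic" and (self.period is None or self.period <= 0):
            raise ValueError(f"periodic axis {self.name!r} must declare a positive period")


@dataclass(frozen=True)
class CVSpace:
    """An ordered collection of CV axes."""

    axes: tuple[Axis, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.axes) < 2:
            raise ValueError("a CV space needs at least 2 axes")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    def check_point(self, p) -> None:
        import numpy as np

        p = np.asarray(p, dtype=float)
        if p.shape[-1] != self.ndim:
            raise DimensionalError(
                f"point of dimension {p.shape[-1]} in {self.ndim}-dimensional CV space"
            )


def rolling_space() -> CVSpace:
    """The embedded CV space of the base-rolling problem.

    Axes are [cos(chi'), sin(chi'), theta]; the first two are linear in
    [-1, 1] and theta is linear in radians.
    """
    return CVSpace(
        (
            Axis("cos_chi", "linear", units="dimensionless"),
            Axis("sin_chi", "linear", units="dimensionless"),
            Axis("theta", "linear", units="rad"),
        )
    )


def plane_space(xname: str = "x", yname: str = "y") -> CVSpace:
    """A generic linear 2D CV space."""
    return CVSpace((Axis(xname), Axis(yname)))
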