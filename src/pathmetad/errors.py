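"""Shared exception types."""


class StateError(RuntimeError):
    """An operation was applied to an object in an invalid state."""


class ParameterError(ValueError):
    """A parameter value is outside its allowed range."""


class RoleError(RuntimeError):
    """A walker attempted an action its role does not permit."""


class PropagationError(RuntimeError):
    """Dynamics produced a non-finite force or left the declared CV bounds."""


class GeometryError(ValueError):
    """Degenerate atomic geometry (e.g. collinear points in a torsion)."""


class SelectionError(KeyError):
    """An atom selector did not resolve to any atom."""


class AccuracyError(RuntimeError):
    """A numerical estimate failed its self-consistency/refinement check."""


class StatisticsError(RuntimeError):
    """Not enough data for the requested statistic."""
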