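"""Exception hierarchy for gatekit."""


class GatekitError(Exception):
    """Base class for all gatekit errors."""


class ConfigurationError(GatekitError):
    """A configuration value violates its documented constraints."""


class StructuralError(GatekitError):
    """Inputs are structurally inconsistent (mismatched dimensions, ids)."""


class SimulationError(GatekitError):
    """A simulation request cannot be satisfied (e.g. unreachable case count)."""


class ClassificationError(GatekitError):
    """A QTL record lacks the fields needed for cis/trans classification."""


class NumericalError(GatekitError):
    """A linear system is singular or an estimate is numerically undefined."""


class InconsistencyError(GatekitError):
    """Estimates violate a required ordering (e.g. r^2 exceeding h2_trans)."""
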