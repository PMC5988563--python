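"""Exception hierarchy for lipidsite."""


class LipidsiteError(Exception):
    """Base class for all lipidsite errors."""


class FormatError(LipidsiteError):
    """A file could not be parsed; the message names the offending line/frame."""


class StructuralError(LipidsiteError):
    """Topology/trajectory structure violates an invariant (bead counts, boxes...)."""


class SelectionError(LipidsiteError, ValueError):
    """An empty or invalid bead/residue selection."""


class ParameterError(LipidsiteError, ValueError):
    """A parameter outside its documented domain."""


class ModeError(ParameterError):
    """Operation called on a trajectory of the wrong resolution (bead vs atom)."""


class EstimationError(LipidsiteError):
    """An estimator has no data to work with (e.g. no interacting lipids)."""


class FitError(EstimationError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(FitError):
    """The curve carries no decay information (residence time exceeds the window)."""


class BootstrapError(EstimationError):
    """Too many bootstrap refits failed for the SD to be meaningful."""
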