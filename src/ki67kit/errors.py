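"""Exception hierarchy for ki67kit.

Validation problems (bad labels, out-of-bounds markers, unscorable HER2
combinations) are kept distinct from I/O problems so the CLI can map them
to different exit codes.
"""


class Ki67KitError(Exception):
    """Base class for all ki67kit errors."""


class AnnotationFormatError(Ki67KitError):
    """A file does not have the expected structure (missing column, bad dialect)."""


class AnnotationValidationError(Ki67KitError):
    """A record violates a domain invariant (unknown label, out-of-bounds marker)."""


class CalibrationError(Ki67KitError):
    """Field calibration is missing or insufficient for the requested unit."""


class EmptyFieldError(Ki67KitError):
    """An IK was requested for a field with zero counted nuclei."""


class HER2UnscorableError(Ki67KitError):
    """A HER2 observation falls outside the printed scoring rule table.

    The scoring rules are stated for specific intensity/continuity/percentage
    combinations; anything else is reported explicitly rather than silently
    defaulted to a score.
    """


class SimulationError(Ki67KitError):
    """A synthetic field could not be generated (e.g. infeasible packing)."""


class MinimumNucleiWarning(UserWarning):
    """A case's total counted nuclei fall below the recommended minimum."""
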