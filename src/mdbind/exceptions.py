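"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`MDBindError`
so callers can catch one type at the CLI boundary.
"""


class MDBindError(Exception):
    """Base class for all package errors."""


class FormatError(MDBindError):
    """A file could not be parsed (message includes the offending line)."""


class StructureError(MDBindError):
    """Frames of a trajectory file disagree in atom count or atom order."""


class SelectionError(MDBindError):
    """A selection expression is malformed."""


class ValidationError(MDBindError):
    """An argument violates a documented precondition."""


class DegenerateFitError(MDBindError):
    """Too few / collinear atoms for a rigid-body superposition."""


class DegeneratePlaneError(MDBindError):
    """Ring atoms are collinear; no plane normal is defined."""


class ProfileAlignmentError(MDBindError):
    """Two fluctuation profiles could not be aligned by residue label."""

    def __init__(self, offending):
        self.offending = list(offending)
        super().__init__(
            "profiles disagree on residue labels: %s" % (self.offending,)
        )


class ConfigError(MDBindError):
    """Run configuration invalid; ``failures`` lists every problem found."""

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {f}" for f in self.failures))
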