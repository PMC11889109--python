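"""Exception hierarchy.

Every error raised by this package derives from :class:`BaseflipError`, so
callers can catch one type at pipeline level while tests can assert on the
specific failure mode.
"""


class BaseflipError(Exception):
    """Root of the package exception hierarchy."""


class FormatError(BaseflipError):
    """A coordinate file could not be interpreted (e.g. zero atoms)."""


class TrajectoryError(BaseflipError):
    """Multi-model structure is not usable as a trajectory."""


class SelectionError(BaseflipError):
    """A selection expression references an unknown field or is malformed."""


class EmptySetError(BaseflipError):
    """An operation that needs atoms received an empty set."""


class MutationError(BaseflipError):
    """Residue mutation requested on an incompatible residue."""


class SchemeError(BaseflipError):
    """A pseudo-dihedral scheme group could not be resolved."""


class AtomLookupError(BaseflipError):
    """A named atom required by a measurement is missing."""


class GeometryError(BaseflipError):
    """A geometric construction failed to reach its target."""

    def __init__(self, msg: str, achieved: float | None = None):
        super().__init__(msg)
        self.achieved = achieved


class PairingError(BaseflipError):
    """Point sets of unequal length passed to a superposition."""


class AlignmentError(BaseflipError):
    """Receptor alignment between two complexes is impossible."""


class StabilityError(BaseflipError):
    """The Langevin integrator produced a divergent step."""
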