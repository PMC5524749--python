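"""Exception hierarchy for ligarray.

Every anticipated failure mode raises a subclass of :class:`LigArrayError`
so that the CLI can catch one type and exit with a message.
"""


class LigArrayError(Exception):
    """Base class for all ligarray errors."""


class AlphabetError(LigArrayError):
    """A residue or IUPAC code outside the allowed alphabet."""


class AlignmentError(LigArrayError):
    """Sequences that should be aligned have unequal lengths."""


class FormatError(LigArrayError):
    """A file does not conform to the expected format."""


class ParameterError(LigArrayError):
    """A parameter value outside its valid domain."""


class CoordinateError(LigArrayError):
    """A probe footprint falls outside the alignment coordinate system."""


class DesignInfeasibleError(LigArrayError):
    """The consensus cannot host any probe pair under the constraints."""


class CapacityError(LigArrayError):
    """More probe sets requested than the array / zip library can hold."""


class DegenerateReplicatesError(LigArrayError):
    """Too few replicate values survive outlier removal."""


class ControlMissingError(LigArrayError):
    """A required control (e.g. the Zip 63 ligation control) is absent."""


class ComponentError(LigArrayError):
    """A template-mix component references an unknown target."""


class RegistryError(LigArrayError):
    """Sample call sets disagree on the target registry."""


class ShapeError(LigArrayError):
    """Two profiles that must align have different shapes."""
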