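"""Exception hierarchy used across the package."""


class LedkitError(Exception):
    """Base class for all ledkit errors."""


class XYZFormatError(LedkitError):
    """Malformed XYZ file (count mismatch, unparsable line)."""


class ElementError(LedkitError):
    """Element symbol not present in the bundled covalent-radius table."""


class ConfigurationError(LedkitError):
    """Invalid user configuration (empty subsystem list, duplicate labels, ...)."""


class LEDParseError(LedkitError):
    """LED output file does not conform to the documented grammar."""


class AlignmentError(LedkitError):
    """Fragment labels could not be aligned between two records."""


class IncompatibilityError(LedkitError):
    """Two records disagree geometrically beyond tolerance."""


class PartitionError(LedkitError):
    """Fragments are not partitioned consistently across records/subsystems."""


class CompletenessError(LedkitError):
    """A required record (e.g. a spanning-pair output) is missing."""


class ConsistencyError(LedkitError):
    """A CalcSpec references fragments absent from the geometry."""


class DegenerateParametersError(LedkitError):
    """Extrapolation parameters make the two-point system singular."""


class MethodError(LedkitError):
    """Operation applied to a record of an incompatible method."""
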