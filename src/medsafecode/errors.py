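"""Exception hierarchy for the Medicine Safety Code toolkit.

All domain errors derive from :class:`MSCError` so callers (and the CLI)
can separate data/validation failures from programming errors.
"""


class MSCError(Exception):
    """Base class for all toolkit errors."""


class KBLoadError(MSCError):
    """Knowledge-base file violates the KB schema; message names the record."""


class KBReferenceError(KBLoadError):
    """A haplotype or rule references an rsid/haplotype not defined in the KB."""


class CapacityError(MSCError):
    """A computation exceeds a configured capacity bound.

    Raised both by the consistency checker (condition references more
    markers than ``max_markers_per_check``) and by QR rendering (URL does
    not fit any symbol version).
    """


class FormatError(MSCError):
    """Genotype input stream is empty or its format cannot be determined."""


class GenotypeParseError(MSCError):
    """Malformed genotype file content (bad line, missing header, ...)."""


class LayoutError(MSCError):
    """A marker cannot be given a code slot (e.g. too many alleles)."""


class EncodeError(MSCError):
    """Profile cannot be encoded against a layout; message names the marker."""


class DecodeError(MSCError):
    """Safety-code payload cannot be decoded.

    ``kind`` is one of ``"alphabet"``, ``"length"``, ``"version"`` or
    ``"index"`` so callers can distinguish the failure mode.
    """

    def __init__(self, message: str, kind: str = "alphabet") -> None:
        super().__init__(message)
        self.kind = kind


class UrlParseError(MSCError):
    """Safety-code URL lacks the /v<major>.<minor>/ version segment."""


class EvaluationError(MSCError):
    """A condition atom references a marker absent from the profile panel."""
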