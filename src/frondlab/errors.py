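"""Exception hierarchy.

Every error raised by frondlab derives from :class:`FrondlabError`, so callers
embedding the library in a larger workflow can catch one base class.
"""


class FrondlabError(Exception):
    """Base class for all frondlab errors."""


class LabwareFormatError(FrondlabError):
    """A labware definition document is malformed (missing/invalid field)."""


class GeometryError(FrondlabError):
    """A geometric constraint is violated (wells outside footprint, off-image tile, ...)."""


class DeckError(FrondlabError):
    """Deck slot misuse: empty slot lookup, occupied slot, no free slot."""


class AddressError(FrondlabError):
    """A well address does not exist in the referenced labware grid."""


class CommandError(FrondlabError):
    """A motion command cannot be serialized or parsed."""


class MachineRangeError(FrondlabError):
    """A commanded target lies outside the machine's axis limits."""


class MachineViolationError(FrondlabError):
    """Raised in strict mode when the virtual machine detects a rule violation."""


class VolumeError(FrondlabError):
    """A liquid-handling volume is negative, exceeds capacity, or underflows."""


class CapacityError(FrondlabError):
    """A container (well, plate set) cannot hold what was requested."""


class LayoutLookupError(FrondlabError):
    """A genotype/media/well lookup failed against a plate layout."""


class SeekError(FrondlabError):
    """Tip-seek travel exhausted without triggering the limit switch."""


class ToolConfigError(FrondlabError):
    """Unknown tool or invalid tool configuration/state."""


class ImageFormatError(FrondlabError):
    """An input image is not the expected RGB format."""


class NameValidationError(FrondlabError):
    """An experiment name contains separator or path characters."""
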