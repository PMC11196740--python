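"""Exception hierarchy.

All domain errors derive from :class:`MultifacetError` so callers (and the
layer-contribution scan, which reports per-row failures) can catch one type.
"""


class MultifacetError(ValueError):
    """Base class for all domain errors raised by this package."""


class UnknownLayerError(MultifacetError, KeyError):
    """A layer name was requested that the multiplex does not contain."""


class NonBinaryLayerError(MultifacetError):
    """An operation requiring 0/1 weights was given a weighted layer."""


class EmptyLayerError(MultifacetError):
    """A layer with zero total weight was used where positive mass is required."""


class DegenerateNullError(MultifacetError):
    """The constructed null network has no mass (e.g. complement of a saturated layer)."""
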