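"""Typed error classes raised by the deterministic pipeline.

Every rejection the sandbox can log maps onto one of these, so callers can
route failures into the structured rejection log instead of aborting a batch.
"""


class DarkTraitsError(Exception):
    """Base class for all package errors."""


class UnparsableNumber(DarkTraitsError):
    """No numeric point estimate survives annotation cleaning."""


class UnknownUnit(DarkTraitsError):
    """A token in the unit string is outside the closed dialect table."""


class AmbiguousUnit(DarkTraitsError):
    """An oxygen-consumption unit with no time dimension cannot be a rate."""


class MissingBodyMass(DarkTraitsError):
    """Whole-body metabolic rate cannot be mass-normalized without body mass."""


class NonPositiveMass(DarkTraitsError):
    """Body mass must be strictly positive."""


class NonPositiveValue(DarkTraitsError):
    """Physical magnitudes (mass, volume) must be strictly positive."""


class ImplausibleTemperature(DarkTraitsError):
    """Experimental temperature outside the biologically plausible range."""


class DuplicatePageIndex(DarkTraitsError):
    """Two extractions claim the same page index within one document."""


class MissingPage(DarkTraitsError):
    """A gap in the 1..N page index sequence of a document."""


class ExtractorFailure(DarkTraitsError):
    """The page extractor raised; surfaced per page, never aborts a document."""


class MalformedBinomial(DarkTraitsError):
    """A species name that does not canonicalize to exactly two tokens."""


class InsufficientData(DarkTraitsError):
    """Fewer observations than a statistic needs (fits, concordance)."""


class InsufficientSamples(DarkTraitsError):
    """t-based confidence intervals need at least two sample values."""


class InsufficientDocuments(DarkTraitsError):
    """The corpus is too small for the requested validation sampling plan."""


class InvalidSpec(DarkTraitsError):
    """A synthetic corpus specification violates its own invariants."""


class IOFailure(DarkTraitsError):
    """Serialization to or from disk failed."""
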