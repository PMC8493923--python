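"""Exception hierarchy for the readiness-index pipeline.

Every error a caller is expected to handle derives from
:class:`ReadinessError`; the subclasses mirror the failure modes of the
pipeline stages (file format, registry configuration, coding, scoring,
item diagnostics, score alignment).
"""


class ReadinessError(Exception):
    """Base class for all package errors."""


class FormatError(ReadinessError):
    """A survey file violates the expected layout (e.g. a required column is missing)."""


class ParseError(ReadinessError):
    """A cell could not be interpreted; carries row/column context in the message."""


class ConfigurationError(ReadinessError):
    """An item registry or index specification is inconsistent with its contract."""


class TierMismatchError(ReadinessError):
    """A facility of the wrong tier was passed to a tier-specific operation."""


class CoverageError(ReadinessError):
    """An index item has no response in any facility record."""


class UndefinedScoreError(ReadinessError):
    """A facility has no applicable items (or no non-empty domains) to score."""


class DegenerateItemError(ReadinessError):
    """An item is constant across facilities, so correlation/IRT quantities are undefined."""

    def __init__(self, item_ids, message=None):
        self.item_ids = list(item_ids)
        super().__init__(message or f"degenerate (constant) items: {self.item_ids}")


class InsufficientDataError(ReadinessError):
    """Too few facilities or items for the requested fit."""


class RescaleError(ReadinessError):
    """Min–max rescaling is undefined because all facilities project to the same raw score."""


class AlignmentError(ReadinessError):
    """Two score sets do not cover the same facilities."""
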