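"""Exception hierarchy shared across the package."""


class PtmEnrichError(Exception):
    """Base class for all package errors."""


class ParseError(PtmEnrichError):
    """Malformed flat-file input.

    Carries ``line_number`` (1-based, where known) and ``entry_name`` of the
    entry being parsed when the problem was detected.
    """

    def __init__(self, message, line_number=None, entry_name=None):
        detail = message
        if line_number is not None:
            detail += f" (line {line_number})"
        if entry_name:
            detail += f" [entry {entry_name}]"
        super().__init__(detail)
        self.line_number = line_number
        self.entry_name = entry_name


class VocabularyError(PtmEnrichError):
    """Inconsistent PTM vocabulary or DAG definition."""


class UnnamedFeatureError(PtmEnrichError):
    """A feature description was empty after normalization."""


class DatabaseError(PtmEnrichError):
    """PTM database construction or lookup failure."""


class ResolutionError(DatabaseError):
    """No query identifier could be matched within the organism partition."""


class ParameterError(PtmEnrichError):
    """A statistical parameter violated its invariant."""
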