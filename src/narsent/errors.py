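"""Exception hierarchy for narsent."""


class NarsentError(Exception):
    """Base class for all package errors."""


class ChatParseError(NarsentError):
    """A CHAT file violates main-tier conventions."""


class SchemaError(NarsentError):
    """A tabular input is missing required columns or fields."""


class ValidationError(NarsentError):
    """A value violates a documented contract (range, enum, uniqueness)."""


class LexiconError(NarsentError):
    """A lexicon file contains conflicting or malformed entries."""
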