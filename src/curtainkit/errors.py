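"""Exception hierarchy shared across the toolkit."""


class CurtainKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CurtainKitError):
    """A column map, annotation, or parameter refers to something absent."""


class FormatError(CurtainKitError):
    """An input file is malformed or empty."""


class ValidationError(CurtainKitError):
    """A value violates a domain invariant (range, alphabet, 1-based index)."""


class MergeError(CurtainKitError):
    """Two files that must be joined share no keys or carry conflicting ones."""


class UnsupportedSchemaError(CurtainKitError):
    """A session document declares a schema version this build cannot load."""
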