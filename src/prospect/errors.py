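"""Exception hierarchy shared across the pipeline."""


class ProspectError(Exception):
    """Base class for all package errors."""


class FormatError(ProspectError):
    """A file violated its expected on-disk format (always names the location)."""


class StateError(ProspectError):
    """An object was used in a way that violates its invariants."""


class ConfigError(ProspectError):
    """Invalid configuration or parameters."""
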