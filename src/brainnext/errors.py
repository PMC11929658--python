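"""Exception hierarchy.  ``BrainNextError`` subclasses are user-facing
(configuration, geometry, I/O); anything else escaping the CLI is internal."""


class BrainNextError(Exception):
    """Base class for user-correctable errors."""


class ConfigurationError(BrainNextError):
    """Invalid configuration value; the message names the offending field."""


class GeometryError(BrainNextError):
    """Incompatible image/patch/network geometry."""


class StratificationError(BrainNextError):
    """A class is too small for the requested stratified split or CV."""
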