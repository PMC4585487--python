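"""Exception types shared across the package."""


class TonocoreError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TonocoreError, ValueError):
    """A parameter violates a documented precondition."""


class LayoutError(TonocoreError, ValueError):
    """A field-layout specification is inconsistent (overlap, empty sheet...)."""


class FormatError(TonocoreError, ValueError):
    """An on-disk input does not match the expected format."""


class StageError(TonocoreError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
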