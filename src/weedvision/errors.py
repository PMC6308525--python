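"""Exception types shared across the package."""


class WeedVisionError(Exception):
    """Base class for package-specific errors."""


class ValidationError(WeedVisionError, ValueError):
    """An input violates a documented precondition."""


class DegenerateImageError(ValidationError):
    """Image has fewer than two occupied gray levels; threshold search is meaningless."""
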