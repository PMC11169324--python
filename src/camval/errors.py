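"""Exception types shared across the pipeline stages."""


class CamvalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CamvalError):
    """Invalid configuration value or combination."""


class PlacementError(CamvalError):
    """A synthetic feature could not be placed inside the allowed geometry."""

    def __init__(self, feature: str, detail: str = ""):
        self.feature = feature
        msg = f"could not place feature {feature!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class RangeError(CamvalError):
    """Slice selection exceeds the available stack."""


class ShapeError(CamvalError):
    """Array dimensions incompatible with the requested layout."""


class AlignmentError(CamvalError):
    """Masks, saliency maps or montages are not pixel-aligned."""


class DataError(CamvalError):
    """Dataset violates a precondition (e.g. single-class training data)."""


class ParseError(CamvalError):
    """Malformed annotation document."""

    def __init__(self, field: str, detail: str = ""):
        self.field = field
        msg = f"invalid annotation field {field!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
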