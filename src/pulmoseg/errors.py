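"""Exception hierarchy shared across the package."""


class PulmosegError(Exception):
    """Base class for all package errors."""


class InputError(PulmosegError):
    """Missing, unreadable, or shape-mismatched input."""


class UnsupportedFormatError(InputError):
    """File exists but is not a format the reader supports."""


class DegenerateInputError(PulmosegError):
    """Input is structurally valid but degenerate for the operation
    (empty sample set, constant image under z-scoring, ...)."""


class DegenerateOutputError(PulmosegError):
    """Operation would produce an unusable result, e.g. a morphological
    shrink that empties the mask."""


class ConfigError(PulmosegError):
    """Invalid configuration value (non-positive bandwidth, bad threshold...)."""


class SpecError(ConfigError):
    """Phantom geometry that cannot be drawn (ellipse outside the image...)."""


class RegistryError(PulmosegError):
    """Unknown plugin identifier (feature extractor, classifier family...)."""
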