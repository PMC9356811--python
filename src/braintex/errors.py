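"""Exception hierarchy shared by all braintex modules.

The command-line layer maps these onto fixed exit codes: configuration
problems exit 2, data problems exit 3, training divergence exits 4.
"""


class BraintexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BraintexError):
    """Invalid or unknown configuration keys/values."""


class FormatError(BraintexError):
    """Unsupported or corrupt file format."""


class DataError(BraintexError):
    """Invalid data passed to a pipeline stage."""


class DegenerateInputError(DataError):
    """Structurally valid input on which the operation is undefined
    (e.g. Otsu on a constant image, a GLCM offset larger than the image)."""


class TrainingError(BraintexError):
    """Raised when optimization diverges; message names the epoch."""


class ModelSchemaError(BraintexError):
    """Serialized model file does not match the documented JSON schema."""
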