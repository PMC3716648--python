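"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems (format, schema, domain) exit 3, numerical failures exit 4.
"""


class IcuglycError(Exception):
    """Base class for all package errors."""


class ConfigError(IcuglycError):
    """Invalid configuration (bad durations, fractions, protocol tables...)."""


class ProtocolError(ConfigError):
    """Malformed sliding-scale insulin protocol (overlapping or gapped bands)."""


class DataError(IcuglycError):
    """Problems with input data."""


class FormatError(DataError):
    """File-level format violation; message names the first offending row."""


class SchemaError(DataError):
    """Record category / column-name mismatch against the declared schema."""


class DomainError(DataError):
    """Value outside its physical domain (e.g. non-positive glucose)."""


class NumericalError(IcuglycError):
    """Numerical failure during training (divergence, non-finite loss)."""
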