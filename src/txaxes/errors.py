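"""Typed exceptions shared across the pipeline.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3.
"""


class TxaxesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TxaxesError):
    """Invalid configuration: bad dimensions, thresholds out of range, etc."""


class DataError(TxaxesError):
    """Malformed or inconsistent input data (parse failures, invariant
    violations such as negative TPM, missing lineage labels)."""
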