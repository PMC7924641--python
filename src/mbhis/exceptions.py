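"""Exception types shared across the pipeline."""


class MBHisError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MBHisError):
    """A parameter or spec object violates its contract."""


class DataError(MBHisError):
    """Input data is malformed or inconsistent with what a stage expects."""
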