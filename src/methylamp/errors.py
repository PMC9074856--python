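"""Exception hierarchy shared across the pipeline stages."""


class MethylampError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MethylampError):
    """Invalid configuration: bad assay files, parameter windows, specs.

    Mapped to exit code 2 by the command-line interface.
    """


class ValidationError(ConfigError):
    """An assay or spec object violates one of its invariants."""


class DataError(MethylampError):
    """Input data cannot be analysed (empty FASTQ, no evaluable molecules...).

    Mapped to exit code 3 by the command-line interface.
    """
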