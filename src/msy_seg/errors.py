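"""Exception types shared across the package."""


class MsySegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MsySegError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MsySegError, ValueError):
    """A malformed input file (VCF / FASTA / TSV subset)."""
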