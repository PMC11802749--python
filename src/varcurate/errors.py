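"""Exception hierarchy shared across the pipeline stages.

Each class maps to a distinct CLI exit code so that shell pipelines can
distinguish misconfiguration from bad input data.
"""


class VarcurateError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(VarcurateError):
    """Invalid or inconsistent configuration (exit code 2)."""

    exit_code = 2


class InputOutputError(VarcurateError):
    """Missing, unreadable, or unwritable files (exit code 3)."""

    exit_code = 3


class FormatError(VarcurateError):
    """Malformed VCF headers, records, or fixture files (exit code 4)."""

    exit_code = 4
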