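"""Typed error hierarchy.

Every malformed input raises one of these; the pipeline never silently
repairs a dataset. The CLI maps each class to a distinct exit code.
"""


class CopathError(Exception):
    """Base class for all copath errors."""

    exit_code = 1


class FormatError(CopathError):
    """A file does not conform to its declared text format."""

    exit_code = 2


class DesignError(CopathError):
    """The experiment design is inconsistent with the data."""

    exit_code = 3


class NormalizationError(CopathError):
    """Size-factor estimation is impossible on this matrix."""

    exit_code = 4


class IncompletenessError(CopathError):
    """A result table is missing required (gene, contrast) rows."""

    exit_code = 5


class SimulationSpecError(CopathError):
    """A simulation specification violates its invariants."""

    exit_code = 6


class ConfigError(CopathError):
    """A run configuration file is invalid."""

    exit_code = 7
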