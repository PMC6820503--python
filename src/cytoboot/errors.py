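"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, data/contract
errors -> 3, analysis errors -> 4.
"""


class CytobootError(Exception):
    """Base class for all package errors."""


class ConfigError(CytobootError):
    """Invalid or inconsistent configuration."""


class FormatError(CytobootError):
    """Malformed input file (FCS, tabular, gates, design)."""


class ContractError(CytobootError):
    """An operation's precondition was violated by its caller."""


class GateError(ContractError):
    """Gating could not be applied (missing marker, overlapping terminals)."""


class ModelError(CytobootError):
    """A statistical model could not be fit (degenerate input, singularity)."""


class AnalysisError(CytobootError):
    """An analysis completed abnormally (e.g. too many failed resamples)."""
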