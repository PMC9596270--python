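"""Exception hierarchy."""


class DeepemoError(Exception):
    """Base class for all package errors."""


class AUFormatError(DeepemoError):
    """An AU CSV lacks a mandatory column or has no parseable header."""


class AUParseError(DeepemoError):
    """A cell in an AU CSV failed numeric conversion."""


class VideoNameError(DeepemoError):
    """A filename does not follow the Celeb-DF naming convention."""


class DuplicateEntryError(DeepemoError):
    """The same video identity was indexed twice."""


class ContractError(DeepemoError):
    """Label sequences and AU tables disagree in length or alignment."""


class ZeroEmotionalBaselineError(DeepemoError):
    """Percentages are undefined: no emotional photograms in the original.

    Routed to the zero-baseline exclusion accounting, never imputed as 0.
    """


class DegenerateProbeError(DeepemoError):
    """Fidelity estimation is undefined: the probe never fired in originals."""


class ConfigError(DeepemoError):
    """Invalid run or simulation configuration."""
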