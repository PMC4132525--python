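"""Exception hierarchy for mokkensep."""


class MokkensepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MokkensepError, ValueError):
    """Invalid user-supplied configuration or parameters."""


class DegenerateDataError(MokkensepError, ValueError):
    """Data too degenerate for the requested computation.

    Raised for constant items, all-identical households, zero margins,
    zero-variance scores and similar conditions under which scalability
    or correlation coefficients are undefined.
    """


class PipelineError(MokkensepError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
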