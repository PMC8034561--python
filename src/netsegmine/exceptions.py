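"""Package-specific exception types."""


class NetsegmineError(Exception):
    """Base class for all package errors."""


class ParseError(NetsegmineError, ValueError):
    """A data file could not be parsed; the message names the offending row."""


class DegeneratePhenotypeError(NetsegmineError, ValueError):
    """The phenotype vector is constant and carries no signal to test."""


class NoMinableEdgesError(NetsegmineError, ValueError):
    """After filtering, no network edge connects two variant-bearing genes."""


class ThresholdFloorError(NetsegmineError, RuntimeError):
    """The candidate-threshold grid was exhausted before the familywise error
    criterion could be met."""

    def __init__(self, floor: float):
        self.floor = floor
        super().__init__(
            f"threshold floor reached: candidate grid exhausted at {floor:.3e} "
            f"while the FWER criterion is still violated"
        )
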