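"""Exception hierarchy for covsize."""


class CovsizeError(Exception):
    """Base class for all covsize errors."""


class ParseError(CovsizeError):
    """A text input (coverage file, FASTQ, histogram, BED) failed to parse."""


class LocusTooShortError(CovsizeError):
    """A locus is too short to survive flank trimming (length <= 2t)."""


class EstimationError(CovsizeError):
    """An estimator could not produce a result (e.g. no loci kept, empty spectrum)."""


class SimulationError(CovsizeError):
    """The simulator was given an infeasible configuration."""
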