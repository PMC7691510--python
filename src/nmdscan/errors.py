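"""Exception hierarchy for nmdscan."""


class NmdscanError(Exception):
    """Base class for all nmdscan errors."""


class TranscriptValidationError(NmdscanError, ValueError):
    """A transcript model violates a structural invariant."""


class TranscriptLoadError(NmdscanError, ValueError):
    """A transcript source could not be parsed into a model."""


class HgvsParseError(NmdscanError, ValueError):
    """A cDNA HGVS string does not match any supported syntax."""

    def __init__(self, message: str, raw: str = "", position: int | None = None):
        super().__init__(message)
        self.raw = raw
        self.position = position


class NotCodingEditError(NmdscanError, ValueError):
    """The HGVS string describes a non-coding (intronic/UTR) change.

    Callers should supply the splice consequence as a TranscriptEdit or a
    protein-level annotation instead.
    """


class UnsupportedProteinHgvsError(NmdscanError, ValueError):
    """A protein HGVS string is not a nonsense or frameshift description."""


class ReferenceMismatchError(NmdscanError, ValueError):
    """A stated reference allele disagrees with the transcript sequence."""

    def __init__(self, position: int, expected: str, found: str):
        super().__init__(
            f"reference mismatch at CDS position {position}: "
            f"variant states {expected!r} but transcript has {found!r}"
        )
        self.position = position
        self.expected = expected
        self.found = found


class NoTerminatorError(NmdscanError, ValueError):
    """A mutant CDS contains no stop codon in its reading frame (stop-loss)."""


class PtcContractError(NmdscanError, ValueError):
    """A PTC lies at or beyond the natural terminator and cannot be classified."""


class UndefinedVafError(NmdscanError, ZeroDivisionError):
    """Allele fraction requested at zero read depth."""


class DegenerateOddsError(NmdscanError, ValueError):
    """DNA allele fraction of 0 or 1: not a heterozygous call, odds undefined."""


class SimulationConfigError(NmdscanError, ValueError):
    """Simulation parameter ranges are infeasible or inconsistent."""
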