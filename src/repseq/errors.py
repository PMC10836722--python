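"""Exception hierarchy shared across the package."""


class RepseqError(Exception):
    """Base class for all package errors."""


class FormatError(RepseqError):
    """An input file does not conform to the expected tabular schema."""


class EmptySampleError(RepseqError):
    """A repertoire file contains no usable rows."""


class ParameterError(RepseqError):
    """An argument violates an operation's precondition."""


class BinningError(RepseqError):
    """Two histograms cannot be compared because their bins differ."""


class AnalysisError(RepseqError):
    """An analysis step cannot produce a defined result for its input."""


class CoverageGapError(AnalysisError):
    """No panel line carries any autologous allele at the queried locus.

    Carries the list of untestable alleles in ``alleles``.
    """

    def __init__(self, message: str, alleles=()):
        super().__init__(message)
        self.alleles = list(alleles)
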