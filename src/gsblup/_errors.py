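"""Exception hierarchy for the gsblup pipeline."""


class GsblupError(Exception):
    """Base class for all gsblup errors."""


class FormatError(GsblupError):
    """Malformed input file: bad cell values, duplicate ids, wrong header."""


class EncodingError(GsblupError):
    """Invalid or inconsistent genotype encoding."""


class IncompatiblePopulationsError(GsblupError):
    """Training and candidate populations share too few (or no) markers."""


class InsufficientDataError(GsblupError):
    """Not enough observations/genotypes to run the requested analysis."""


class ConvergenceError(GsblupError):
    """A REML fit failed to converge or produced non-finite quantities."""


class ImputationError(GsblupError):
    """Missing-data structure makes KNN imputation impossible."""


class DegenerateGenotypesError(GsblupError):
    """All markers monomorphic: no relationship matrix can be built."""


class AlignmentError(GsblupError):
    """Phenotyped individuals absent from the kinship/genotype matrix."""


class FoldSizeError(GsblupError):
    """Cross-validation fold too small for the requested k."""
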