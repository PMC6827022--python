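"""Exception hierarchy for capskit."""


class CapskitError(Exception):
    """Base class for all capskit errors."""


class ParameterError(CapskitError, ValueError):
    """Invalid parameter value (simulation or analysis settings)."""


class LabelingError(CapskitError):
    """A VCF sample has no species label, or label table is malformed."""


class InputConsistencyError(CapskitError):
    """Conflicting information between input files (e.g. two REF alleles at one coordinate)."""


class FormatError(CapskitError):
    """Malformed input file (VCF / GFF3 / TSV)."""


class PreconditionError(CapskitError):
    """Operation called on a site that did not pass the candidate-site filter."""


class DegenerateSiteError(CapskitError):
    """Site has no non-missing genotype calls."""


class ThresholdError(CapskitError):
    """Score distribution too degenerate to derive a threshold."""


class GenerationError(CapskitError):
    """Synthetic data could not be generated under the given constraints."""


class CoordinateError(CapskitError, IndexError):
    """Position outside the reference sequence."""


class NoProductError(CapskitError):
    """In-silico PCR found no amplicon for the primer pair."""


class AmbiguousPrimerError(CapskitError):
    """In-silico PCR found more than one primer binding site / product."""
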