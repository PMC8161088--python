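"""Exception hierarchy shared across the package."""


class RegLocusError(Exception):
    """Base class for all reglocus errors."""


class FormatError(RegLocusError):
    """A file or record does not conform to the expected format."""


class DegenerateInputError(RegLocusError):
    """Input is structurally valid but the requested statistic is undefined on it
    (e.g. constant dosage, monomorphic genotype counts, zero margin)."""


class InsufficientDataError(RegLocusError):
    """Too few observations for the requested test."""


class AlignmentError(RegLocusError):
    """Two records that must describe the same variant/allele pair do not."""


class InputError(RegLocusError):
    """Inconsistent user-supplied values (e.g. a frequency implying more alleles
    than the sample holds)."""
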