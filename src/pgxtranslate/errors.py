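"""Exception hierarchy for pgxtranslate.

All package-specific failures derive from :class:`PgxError` so callers
(notably the CLI) can distinguish data problems from programming bugs.
"""


class PgxError(Exception):
    """Base class for all pgxtranslate errors."""


class TableFormatError(PgxError):
    """A haplotype table source is malformed (ragged rows, duplicates, empty)."""


class EmptyTableError(PgxError):
    """Curation or loading left no usable variants for a gene."""


class UnsupportedVariantError(PgxError):
    """A variant carries more distinct minor alleles than the code set supports."""


class AnnotationConflictError(PgxError):
    """Two gene tables define the same rsID inconsistently."""


class UnknownAlleleError(PgxError):
    """A sample carries an allele not present in the variant annotation."""


class VcfFormatError(PgxError):
    """A VCF input is unreadable or lacks required fields."""


class FilterError(PgxError):
    """An rsID restriction list contains no valid entries."""


class ReportError(PgxError):
    """Translation report writing failed or had nothing to write."""


class UpdateError(PgxError):
    """A knowledge-base update (new haplotype / new gene table) is invalid."""


class ConsistencyError(PgxError):
    """Internal vector-length or bookkeeping mismatch; indicates a bug upstream."""
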