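"""Exception hierarchy shared across the package."""


class TxAdviseError(Exception):
    """Base class for all txadvise errors."""


class GtfParseError(TxAdviseError):
    """A GTF line could not be parsed; message names the offending line number."""


class ValidationError(TxAdviseError):
    """A domain object violates its invariants (bad exon order, duplicate ids, ...)."""


class AdapterError(TxAdviseError):
    """An assembler invocation failed (nonzero exit, timeout, missing output)."""
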