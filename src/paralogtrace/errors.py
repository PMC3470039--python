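"""Exception hierarchy shared across the pipeline.

Validation errors signal inputs that parse but violate a domain invariant
(duplicate ids, out-of-range probabilities, exons outside their gene).
Format errors signal files that cannot be interpreted at all (ragged
alignments, wrong column counts). The CLI maps these onto distinct exit
codes so batch callers can tell a bad parameter from a bad file.
"""


class ParalogtraceError(Exception):
    """Base class for all package errors."""


class ValidationError(ParalogtraceError, ValueError):
    """Input parsed but violates a domain invariant."""


class FormatError(ParalogtraceError, ValueError):
    """Input file is not in the expected format."""


class LookupError_(ParalogtraceError, KeyError):
    """A requested id is absent from the queried container."""
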