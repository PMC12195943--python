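"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`CapripepError` so
callers (and the CLI) can distinguish expected input problems from bugs.
"""


class CapripepError(Exception):
    """Base class for all capripep errors."""


class FastaParseError(CapripepError):
    """Malformed FASTA input; the message names the offending line."""


class SequenceValidationError(CapripepError):
    """A residue string contains characters outside the allowed alphabet."""


class EditError(CapripepError):
    """Base for variant-edit problems."""


class EditConflictError(EditError):
    """The reference residue recorded in an edit does not match the sequence."""


class EditRangeError(EditError):
    """An edit position falls outside the reference sequence."""


class NotComparableError(CapripepError):
    """Two sequences differ by more than the supported edit structure."""


class ConfigError(CapripepError):
    """A configuration file (enzyme table, edit list, pipeline) is invalid."""


class FormatError(CapripepError):
    """A tabular input file has missing or unexpected columns."""


class ValidationError(CapripepError):
    """A tabular input file has an invalid value; the message names the row."""


class UsageError(CapripepError):
    """An API call with arguments that cannot be honoured (e.g. unknown
    activity code, gene mismatch)."""


class SpecError(CapripepError):
    """A synthetic-data specification is infeasible."""
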