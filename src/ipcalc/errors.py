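"""Exception hierarchy for ipcalc."""


class IpcalcError(Exception):
    """Base class for all ipcalc errors."""


class UnknownPkaSetError(IpcalcError, KeyError):
    """Requested pKa set name is not registered."""


class PkaConfigError(IpcalcError, ValueError):
    """A pKa config file is missing groups or holds out-of-range values."""


class EmptySequenceError(IpcalcError, ValueError):
    """Sequence is empty after stripping whitespace."""


class NoIonizableGroupsError(IpcalcError, ValueError):
    """No ionizable group present; net charge is identically zero."""


class NoRootError(IpcalcError, ValueError):
    """Net charge keeps a constant sign on the pH bracket [0, 14]."""


class MalformedFastaError(IpcalcError, ValueError):
    """FASTA input has sequence data before the first header line."""


class EmptyPanelError(IpcalcError, ValueError):
    """A consensus panel of pKa sets is empty."""


class DatasetError(IpcalcError, ValueError):
    """Dataset violates a precondition (too few records, missing labels...)."""
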