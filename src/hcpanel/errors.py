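"""Exception hierarchy shared across the pipeline."""


class HcPanelError(Exception):
    """Base class for all package errors."""


class InputError(HcPanelError):
    """A record violates a type invariant or an operation precondition."""


class FormatError(HcPanelError):
    """A file cannot be parsed: missing columns, bad field values, etc."""


class ParseError(HcPanelError):
    """An HGVS description uses a form the parser does not support."""


class StructuralError(HcPanelError):
    """A pedigree is internally inconsistent (dangling parents, probands)."""


class ConfigError(HcPanelError):
    """A configuration file or simulation plan is invalid or infeasible."""
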