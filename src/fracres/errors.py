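"""Exception hierarchy for the fracres pipeline.

Stages raise the narrowest class that applies; the pipeline catches
:class:`FracresError` at stage boundaries and re-raises with the stage name.
"""


class FracresError(Exception):
    """Base class for all fracres errors."""


class InputError(FracresError):
    """A required input file is missing or unreadable."""


class FormatError(FracresError):
    """An input file is readable but structurally malformed (e.g. a cyclic
    ontology, or a term with no path to any root)."""


class ConfigError(FracresError):
    """Configuration is inconsistent with the data (e.g. a functional-scheme
    GO term absent from the ontology, or invalid simulation parameters)."""


class ValidationError(FracresError):
    """Data values violate a stage precondition (e.g. an all-zero copy-count
    family, an out-of-range retention index, an incomplete design)."""
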