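"""Exception taxonomy.

Separated so the CLI can map error classes onto distinct exit codes.
"""


class BasicPathwaysError(Exception):
    """Base class for all package errors."""


class ModelValidationError(BasicPathwaysError):
    """A model file or model object violates the schema or an invariant."""


class MatrixIOError(BasicPathwaysError):
    """A matrix TSV file is malformed or labels do not match dimensions."""


class DegeneracyError(BasicPathwaysError):
    """A row of the internal stoichiometry has no strictly positive entry.

    The metabolite behind such a row can only be consumed or diluted, so its
    steady-state concentration is forced to zero. The caller should run
    network reduction first and inspect what was removed.
    """


class DomainError(BasicPathwaysError):
    """An argument is outside the mathematical domain of an operation."""
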