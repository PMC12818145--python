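"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`SpecificationError` and
:class:`SchemaError` -> 2 (bad model/data specification),
:class:`NumericalError` subclasses -> 3 (degeneracy in the numbers).
"""


class PlsIpaError(Exception):
    """Base class for all package errors."""


class SpecificationError(PlsIpaError):
    """The model specification is invalid (unknown names, cycles, duplicates)."""


class CycleError(SpecificationError):
    """The structural graph contains a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "structural model must be recursive (acyclic); found cycle: "
            + " -> ".join(self.cycle + [self.cycle[0]])
        )


class SchemaError(PlsIpaError):
    """Data does not match the model (missing columns, non-numeric cells)."""


class NumericalError(PlsIpaError):
    """Base class for numerical/degeneracy failures."""


class DegenerateDataError(NumericalError):
    """Zero-variance column, rank-0 block, or similar degeneracy."""


class SingularityError(NumericalError):
    """Perfectly collinear predictor scores in a structural equation."""


class AdmissibilityError(NumericalError):
    """A generator configuration implies a negative disturbance variance."""


class OutOfRangeError(NumericalError):
    """Observed value falls outside declared theoretical bounds."""
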