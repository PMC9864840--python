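"""Exception hierarchy for ecmkit."""


class EcmkitError(Exception):
    """Base class for all ecmkit errors."""


class GPRSyntaxError(EcmkitError):
    """Malformed gene-protein-reaction rule text."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnsupportedGPRError(EcmkitError):
    """GPR shape the isozyme splitter does not support (OR nested under AND)."""


class ModelIntegrityError(EcmkitError):
    """A model references undeclared metabolites/genes or violates invariants."""


class ModelParseError(EcmkitError):
    """A model file could not be parsed."""


class FormulaError(EcmkitError):
    """An elemental formula contains an unknown element or bad syntax."""


class AmbiguousBiomassError(EcmkitError):
    """More than one formula-less species: biomass cannot be identified."""


class NormalizationError(EcmkitError):
    """Macromolecule normalization impossible (non-positive implied mass)."""


class LookupError_(EcmkitError):
    """A gene or reaction required by an operation is missing from a table."""


class DegenerateDataError(EcmkitError):
    """Input table degenerate (e.g. zero total proteome mass)."""


class EmptyConstraintError(EcmkitError):
    """No reaction carries both a kcat and an MW: the enzyme budget row is empty."""


class SolverError(EcmkitError):
    """The LP solver failed in a way that is not plain infeasibility."""
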