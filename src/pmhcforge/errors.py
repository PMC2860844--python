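"""Exception hierarchy shared across the package."""


class PmhcError(Exception):
    """Base class for all package errors."""


class PDBParseError(PmhcError):
    """A coordinate file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PDBWriteError(PmhcError):
    """A structure cannot be serialized to the fixed-column format."""


class AmbiguousPeptideError(PmhcError):
    """Zero or several candidate peptide chains; carries the candidate list."""

    def __init__(self, message: str, candidates: list[str]):
        self.candidates = list(candidates)
        super().__init__(f"{message} (candidates: {candidates})")


class IncompleteBackboneError(PmhcError):
    """A peptide residue is missing one of N, CA, C, O."""


class SuperpositionError(PmhcError):
    """Point sets cannot be superposed (size mismatch, degeneracy, unalignable chains)."""


class ThreadingError(PmhcError):
    """Target sequence cannot be threaded onto the template."""


class ScoringError(PmhcError):
    """Missing parameters or invalid state during energy evaluation."""


class FixtureError(PmhcError):
    """Invalid synthetic-fixture specification."""
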