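"""Exception hierarchy shared across the package."""


class VillimorphError(Exception):
    """Base class for all package errors."""


class SWCFormatError(VillimorphError):
    """Raised when an SWC file violates the format contract.

    Carries the offending line number when one can be identified.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TreeStructureError(VillimorphError):
    """Raised when a tree violates structural invariants (cycles, multiple roots)."""


class DegenerateGeometryError(VillimorphError):
    """Raised when a geometric quantity is undefined (e.g. coincident endpoints)."""


class ManifestError(VillimorphError):
    """Raised for inconsistent cohort manifests (e.g. conflicting group labels)."""


class GenerationError(VillimorphError):
    """Raised when the synthetic generator cannot realize a requested geometry."""
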