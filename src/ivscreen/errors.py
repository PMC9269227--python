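"""Exception hierarchy for the screening pipeline.

Every failure mode a caller may want to catch individually gets its own
class; all inherit from :class:`IVScreenError` so batch drivers can catch
the family while letting programming errors propagate.
"""


class IVScreenError(Exception):
    """Base class for all pipeline errors."""


class StructureError(IVScreenError):
    """A molecular structure string or file could not be parsed."""


class InsufficientDecoysError(IVScreenError):
    """Fewer eligible decoy candidates than requested."""

    def __init__(self, query_id: str, needed: int, found: int):
        self.query_id = query_id
        self.needed = needed
        self.found = found
        super().__init__(
            f"decoy selection for {query_id!r}: needed {needed} eligible "
            f"candidates, found {found} (shortfall {needed - found})"
        )


class DegenerateStructureError(IVScreenError):
    """A receptor is empty (or effectively empty) after cleaning."""


class DegenerateLigandError(IVScreenError):
    """A co-crystallized hetero group is too small to define a site."""


class ParameterError(IVScreenError):
    """An operation was configured with an out-of-range parameter."""


class EngineError(IVScreenError):
    """A docking engine invocation failed; carries job identity."""

    def __init__(self, message: str, compound_id: str = "?", pdb_id: str = "?"):
        self.compound_id = compound_id
        self.pdb_id = pdb_id
        super().__init__(f"[{compound_id}/{pdb_id}] {message}")


class BatchError(IVScreenError):
    """Every job in a docking batch failed."""


class NormalizationError(IVScreenError):
    """V = V0/VR could not be formed (no decoys, or non-negative VR)."""


class TypingError(IVScreenError):
    """Pose atoms lack the element/donor/acceptor typing detection needs."""
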