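"""Package-specific exception types."""


class AerotraitsError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(AerotraitsError, ValueError):
    """An argument is non-finite or outside its physical domain."""


class InvalidTraitError(AerotraitsError, ValueError):
    """A trait value violates its invariant (e.g. non-positive A_eco)."""


class EmptyHabitatError(AerotraitsError, ValueError):
    """A trait combination yields no habitable grid cells."""


class SpeciesSkippedError(AerotraitsError):
    """A species cannot be fitted; carries a machine-readable reason."""

    def __init__(self, species_id: str, reason: str, detail: str = ""):
        self.species_id = species_id
        self.reason = reason
        self.detail = detail
        msg = f"species {species_id!r} skipped: {reason}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SchemaError(AerotraitsError, ValueError):
    """A file does not match the expected schema (columns/variables/units)."""


class NewickParseError(AerotraitsError, ValueError):
    """Malformed Newick input."""


class SingularCovarianceError(AerotraitsError, ValueError):
    """Phylogenetic covariance matrix is singular or ill-conditioned."""
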