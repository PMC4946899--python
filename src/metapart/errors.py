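"""Exception hierarchy for metapart."""


class MetapartError(Exception):
    """Base class for all package-specific errors."""


class SizeLimitError(MetapartError, ValueError):
    """A requested enumeration exceeds the supported size (N > 20)."""


class UnpricedGenomeError(MetapartError, KeyError):
    """A genome appears in a community but has no entry in the cost table."""


class UncoveredSubstrateError(MetapartError, ValueError):
    """A species set does not jointly cover all substrates.

    Carries the list of uncovered (0-based) substrate indices in
    ``missing``.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"substrates not covered by any species: {self.missing}"
        )


class InfiniteHarvestError(MetapartError, ValueError):
    """An operation requiring finite harvests met an unconsumed substrate."""


class ConvergenceError(MetapartError, RuntimeError):
    """An iterative solver failed; carries the last good state if any."""

    def __init__(self, message, last_state=None):
        self.last_state = last_state
        super().__init__(message)


class ConsistencyError(MetapartError, RuntimeError):
    """Two independent solution routes disagree beyond tolerance (bug trap)."""


class DegenerateModelError(MetapartError, RuntimeError):
    """Support enumeration found no valid equilibrium support."""


class UndefinedSimilarityError(MetapartError, ValueError):
    """Similarity requested for a community with zero total abundance."""


class CommunityValidationError(MetapartError, ValueError):
    """A community table failed validation; names the offending row."""
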