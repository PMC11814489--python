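"""Exception hierarchy.

Every user-facing failure mode has a dedicated type so the CLI can map it to
a meaningful exit message and tests can assert on the precise failure.
"""


class AnnoflowError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AnnoflowError):
    """Input data violates a structural requirement (NaN, shape mismatch, ...)."""


class ConfigurationError(AnnoflowError):
    """A parameter or name refers to something that does not exist or is inconsistent."""


class FormatError(AnnoflowError):
    """An on-disk file does not have the expected structure."""


class EmptySubsetError(AnnoflowError):
    """A subset operation matched zero cells."""


class EmptySelectionError(AnnoflowError):
    """A node/link selection resolved to zero cells."""


class AllFilteredError(AnnoflowError):
    """Link/node filtering removed everything.

    Carries ``max_viable_threshold``: the largest ``min_cells`` value at which
    at least one link would survive the fixed-point filter.
    """

    def __init__(self, message: str, max_viable_threshold: int):
        super().__init__(message)
        self.max_viable_threshold = max_viable_threshold
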