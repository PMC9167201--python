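"""Exception types shared across the package."""


class NetsigError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(NetsigError):
    """A synthetic design violates its preconditions (e.g. zero counts)."""


class GenerationError(NetsigError):
    """Random generation failed to satisfy structural constraints after
    a bounded number of attempts (e.g. edge density too low to connect)."""


class UnknownGeneError(NetsigError):
    """A requested gene is absent from the network or expression matrix."""


class NetworkBuildError(NetsigError):
    """Network assembly produced an empty or inconsistent graph."""
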