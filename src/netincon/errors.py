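"""Exception hierarchy shared across the package."""


class NetinconError(Exception):
    """Base class for all package-specific errors."""


class InvalidNetworkError(NetinconError, ValueError):
    """A treatment set or design set violates its structural requirements."""


class InvalidOrderingError(NetinconError, ValueError):
    """A treatment ordering is not a permutation of the network's treatments."""


class IncompatiblePartitionsError(NetinconError, ValueError):
    """Two partitions do not cover the same design set."""


class NotSeparableError(NetinconError, ValueError):
    """A design cannot be separated from itself."""


class StructuralError(NetinconError, ValueError):
    """A dataset layout is inconsistent with the model it is paired with."""


class IncompatibleLayoutError(NetinconError, ValueError):
    """Two design matrices were not built on the same contrast rows."""


class RankDeficiencyError(NetinconError, ValueError):
    """The weighted normal equations are singular."""


class SaturatedModelError(NetinconError, ValueError):
    """Zero residual degrees of freedom: heterogeneity cannot be estimated."""


class ConfigError(NetinconError, ValueError):
    """A simulation configuration is internally inconsistent."""


class ParseError(NetinconError, ValueError):
    """A data file violates the declared dialect."""
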