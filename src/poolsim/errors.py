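"""Exception hierarchy for poolsim."""


class PoolsimError(Exception):
    """Base class for all poolsim errors."""


class ParameterError(PoolsimError, ValueError):
    """Invalid simulation or model parameter (negative variance, |rho| > 1, ...)."""


class ComputationError(PoolsimError, RuntimeError):
    """A quantity could not be computed (degenerate spread, empty 2x2 cell, ...)."""


class InsufficientStratumError(PoolsimError, ValueError):
    """A sampling stratum is smaller than the number of members it must supply."""

    def __init__(self, stratum: str, available: int, required: int):
        self.stratum = stratum
        self.available = available
        self.required = required
        super().__init__(
            f"stratum {stratum!r} has {available} viable members but "
            f"{required} are required"
        )


class PartitionError(PoolsimError, ValueError):
    """A cohort cannot be split into pools of the requested size."""


class RankDeficiencyError(PoolsimError, ValueError):
    """The regression design matrix is not of full column rank."""


class UndefinedMetricError(PoolsimError, ValueError):
    """A summary metric is undefined (no replicates, no stable fits, ...)."""
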