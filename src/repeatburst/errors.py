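"""Exception hierarchy.

Each family maps to a distinct CLI exit code so that shell pipelines can
distinguish bad input from a failed simulation or a failed fit.
"""


class RepeatBurstError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(RepeatBurstError):
    """Malformed user input: bad FASTA, invalid alphabet, length mismatch."""

    exit_code = 2


class DomainError(RepeatBurstError, ValueError):
    """Parameter outside the model's domain (negative time, 2*n_cpg > L, ...)."""

    exit_code = 2


class NoPowerLawTailError(DomainError):
    """The existence condition mu*k < delta*gamma is violated.

    For such k the abundance distribution has no power-law tail and the
    exponent alpha(k) is undefined; downstream fits must exclude these k.
    """

    exit_code = 2


class SimulationError(RepeatBurstError):
    """Kinetic Monte Carlo failure (e.g. target size unreachable)."""

    exit_code = 3


class EstimationError(RepeatBurstError):
    """An estimator could not be computed (too few tail points, no convergence)."""

    exit_code = 4
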