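"""Exception hierarchy shared across the package."""


class HeightrezError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HeightrezError, ValueError):
    """A simulation or estimation parameter violates its contract."""


class DataError(HeightrezError, ValueError):
    """Input data violate a contract (bad dosages, misaligned ids, ...)."""


class DesignError(HeightrezError, ValueError):
    """A survey design is unusable for variance estimation."""


class RankDeficiencyError(HeightrezError, ValueError):
    """A fixed-effects design matrix is not full column rank."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(HeightrezError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


class RubricError(HeightrezError, ValueError):
    """A scoring rubric is internally inconsistent (gaps, overlaps, range)."""
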