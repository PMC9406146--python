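"""Exception types shared across the package."""


class PepAggError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(PepAggError, ValueError):
    """A peptide sequence contains a letter outside the 20 canonical residues."""


class PeptideTableError(PepAggError, ValueError):
    """Structured parse error for peptide tables; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class EnsembleFormatError(PepAggError, ValueError):
    """Coordinate/metadata files are inconsistent or malformed."""


class ShortTrajectoryError(PepAggError, ValueError):
    """A trajectory is shorter than the requested analysis window."""

    def __init__(self, traj_id: int, length: int, required: int):
        self.traj_id = traj_id
        super().__init__(
            f"trajectory {traj_id} has {length} frames, "
            f"window requires at least {required}"
        )


class ConvergenceError(PepAggError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (residual {residual:.3e})"
        super().__init__(message)


class OutOfRangeError(PepAggError, ValueError):
    """A requested crossing/midpoint lies outside the evaluated grid.

    ``side`` is ``"above grid"`` or ``"below grid"``.
    """

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"midpoint crossing lies {side}")
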