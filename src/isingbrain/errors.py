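"""Exception types shared across the package."""


class IsingBrainError(Exception):
    """Base class for package errors."""


class InvalidLatticeError(IsingBrainError, ValueError):
    """Lattice is not a square grid of -1/+1 spins."""


class InvalidTemperatureError(IsingBrainError, ValueError):
    """Temperature must be strictly positive."""


class InvalidBlockError(IsingBrainError, ValueError):
    """Block size incompatible with the lattice side."""


class AsymmetricCropError(IsingBrainError, ValueError):
    """Central crop would remove an unequal number of rows per side."""


class InvalidKError(IsingBrainError, ValueError):
    """kNN neighbour count out of range."""


class ConfigError(IsingBrainError, ValueError):
    """Inconsistent configuration (split sizes, empty splits, ...)."""


class ShapeError(IsingBrainError, ValueError):
    """Input dimensionality does not match what a model expects."""


class TrainingDivergedError(IsingBrainError, RuntimeError):
    """Non-finite loss during optimisation."""

    def __init__(self, message, checkpoint=None):
        super().__init__(message)
        self.checkpoint = checkpoint


class UndefinedCorrelationError(IsingBrainError, ValueError):
    """Correlation undefined because one input has zero variance."""


class CollinearityError(IsingBrainError, ValueError):
    """Rank-deficient design matrix in a regression."""

    def __init__(self, message, column=None):
        super().__init__(message)
        self.column = column


class DegenerateResampleError(IsingBrainError, RuntimeError):
    """Bootstrap resample stayed degenerate after the redraw cap."""
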