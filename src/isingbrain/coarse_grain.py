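"""Coarse-graining of spin lattices into block time series and connectivity matrices.

A recorded lattice series is averaged over b x b blocks (floor division of the
side, trailing rows/columns discarded), which turns the binary spins into a
continuous signal per block — the lattice analogue of a regional BOLD time
series. Pairwise Pearson correlation of the block series yields a symmetric
connectivity matrix with unit diagonal, and a central crop reduces it to the
target node count (333 for the standard presets), trimming boundary blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AsymmetricCropError, InvalidBlockError
from .ising_sim import LatticeSeries, SimulationConfig, simulate

__all__ = [
    "BlockSeries",
    "SimPreset",
    "PRESETS",
    "block_average",
    "pearson_connectivity",
    "central_crop",
    "ising_connectivity",
    "save_matrix",
    "load_matrix",
]


@dataclass
class BlockSeries:
    """Continuous block signals: values is (n_blocks, n_time), entries in [-1, 1]."""

    values: np.ndarray
    block_size: int
    grid_side: int

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


def block_average(series: LatticeSeries | np.ndarray, block_size: int) -> BlockSeries:
    """Average each snapshot over non-overlapping block_size x block_size blocks.

    The side is floor-divided: grid_side = L // block_size, and the trailing
    L - grid_side*block_size rows/columns are discarded. Row-major block order
    gives grid_side**2 block series of length n_record.
    """
    snaps = series.snapshots if isinstance(series, LatticeSeries) else np.asarray(series)
    if snaps.ndim == 2:
        snaps = snaps[None]
    L = snaps.shape[1]
    if block_size < 1 or block_size > L:
        raise InvalidBlockError(f"block_size {block_size} incompatible with L={L}")
    g = L // block_size
    m = g * block_size
    cropped = snaps[:, :m, :m].astype(np.float64)
    blocks = cropped.reshape(snaps.shape[0], g, block_size, g, block_size).mean(axis=(2, 4))
    return BlockSeries(blocks.reshape(snaps.shape[0], g * g).T.copy(), block_size, g)


def pearson_connectivity(series: BlockSeries | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of row-wise time series.

    Zero-variance rows have undefined correlations; those entries are set to
    0 (diagonal stays 1) and a warning is emitted — frozen blocks can occur at
    the low end of the training temperature range.
    """
    values = series.values if isinstance(series, BlockSeries) else np.asarray(series, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2D (n_series, n_time>=2) array")
    sd = values.std(axis=1)
    flat = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance series; their correlations set to 0",
            stacklevel=2,
        )
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def central_crop(matrix: np.ndarray, target: int) -> np.ndarray:
    """Keep the central target x target block of a square matrix.

    (N - target)/2 leading and trailing rows/columns are removed; an odd
    difference is refused rather than split unevenly.
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if target > n:
        raise ValueError(f"target {target} exceeds matrix size {n}")
    if (n - target) % 2:
        raise AsymmetricCropError(f"cannot crop {n} -> {target}: difference is odd")
    off = (n - target) // 2
    return matrix[off : off + target, off : off + target].copy()


@dataclass(frozen=True)
class SimPreset:
    """Lattice/coarse-graining geometry used throughout a study.

    ``full`` is the full-scale geometry (250 -> 19x19 blocks of 13 -> 333
    nodes). ``small`` keeps the output dimensionality (114 -> 19x19 blocks of
    6 -> 333 nodes) at a fraction of the cost, for tests and desk-scale runs.
    """

    name: str
    L: int
    block_size: int
    target_n: int
    burn_in: int
    n_record: int = 200

    def config(self, T: float, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            L=self.L, T=T, burn_in=self.burn_in, n_record=self.n_record, seed=seed
        )


PRESETS: dict[str, SimPreset] = {
    "full": SimPreset("full", L=250, block_size=13, target_n=333, burn_in=1000),
    "small": SimPreset("small", L=114, block_size=6, target_n=333, burn_in=500),
    # tiny geometry for unit tests: 24 -> 6x6 blocks of 4 -> 32 nodes
    "tiny": SimPreset("tiny", L=24, block_size=4, target_n=32, burn_in=100, n_record=60),
}


def ising_connectivity(
    config: SimulationConfig,
    block_size: int,
    target_n: int,
) -> np.ndarray:
    """simulate -> block_average -> pearson_connectivity -> central_crop."""
    g = config.L // block_size
    if g * g < target_n:
        raise ValueError(f"{g}x{g} blocks cannot supply {target_n} nodes")
    series = simulate(config)
    blocks = block_average(series, block_size)
    return central_crop(pearson_connectivity(blocks), target_n)


def save_matrix(matrix: np.ndarray, path, header: bool = False) -> None:
    """Write a connectivity matrix as delimited text (or .npz if so suffixed)."""
    path = str(path)
    if path.endswith(".npz"):
        np.savez_compressed(path, matrix=matrix)
        return
    kw = {"delimiter": ",", "fmt": "%.17g"}
    if header:
        kw["header"] = ",".join(f"n{i}" for i in range(matrix.shape[1]))
        kw["comments"] = ""
    np.savetxt(path, matrix, **kw)


def load_matrix(path, header: bool = False) -> np.ndarray:
    path = str(path)
    if path.endswith(".npz"):
        return np.load(path)["matrix"]
    return np.loadtxt(path, delimiter=",", skiprows=1 if header else 0)
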