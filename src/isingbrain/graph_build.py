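"""kNN graph construction from connectivity matrices and labelled dataset assembly.

Each node is a coarse-grained block (or cortical ROI); its feature vector is
its full row of the signed connectivity matrix. Edges connect every node to
its k strongest neighbours — ranked by absolute correlation by default, so
strong anticorrelations also count as proximity — and the edge set is the
union over endpoints, so every node keeps degree >= k. Edges are unweighted;
the correlation weights live in the node features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coarse_grain import PRESETS, SimPreset, ising_connectivity
from .errors import ConfigError, InvalidKError

__all__ = ["ROIGraph", "LabeledGraphDataset", "knn_graph", "build_dataset", "save_dataset", "load_dataset"]


@dataclass
class ROIGraph:
    """A kNN graph over connectivity nodes.

    node_features is (n_nodes, n_nodes): row i holds the signed correlation of
    node i with every node. edges is (n_edges, 2) with i < j, no self-loops.
    """

    node_features: np.ndarray
    edges: np.ndarray
    k: int

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


def knn_graph(conn: np.ndarray, k: int, rank_by: str = "abs") -> ROIGraph:
    """Connect each node to its k strongest neighbours, union-symmetrised.

    rank_by "abs" (default) ranks neighbours by |r|; "signed" ranks by r.
    Ties are broken toward the lower node index so builds are deterministic.
    """
    conn = np.asarray(conn, dtype=np.float64)
    n = conn.shape[0]
    if conn.ndim != 2 or conn.shape[1] != n:
        raise ValueError(f"connectivity must be square, got {conn.shape}")
    if not 1 <= k < n:
        raise InvalidKError(f"need 1 <= k < {n}, got k={k}")
    if rank_by not in ("abs", "signed"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    score = np.abs(conn) if rank_by == "abs" else conn.copy()
    np.fill_diagonal(score, -np.inf)  # self never a neighbour
    # stable argsort on -score keeps lower indices first among ties
    order = np.argsort(-score, axis=1, kind="stable")[:, :k]
    src = np.repeat(np.arange(n), k)
    dst = order.ravel()
    pairs = np.sort(np.stack([src, dst], axis=1), axis=1)
    pairs = np.unique(pairs, axis=0)
    return ROIGraph(conn.copy(), pairs, k)


@dataclass
class LabeledGraphDataset:
    """Graphs with their generating temperatures and a train/val/test split."""

    graphs: list[ROIGraph]
    labels: np.ndarray
    split: np.ndarray  # array of "train" | "val" | "test"
    seed: int
    preset: str = "small"
    k: int = 10
    meta: dict = field(default_factory=dict)

    def subset(self, tag: str) -> tuple[list[ROIGraph], np.ndarray]:
        idx = np.flatnonzero(self.split == tag)
        return [self.graphs[i] for i in idx], self.labels[idx]

    def __len__(self) -> int:
        return len(self.graphs)


def build_dataset(
    n_sims: int,
    t_low: float = 1.8,
    t_high: float = 2.5,
    split_sizes: tuple[int, int, int] = (1000, 250, 250),
    preset: str | SimPreset = "full",
    k: int = 10,
    seed: int = 0,
    rank_by: str = "abs",
) -> LabeledGraphDataset:
    """Simulate n_sims connectivity graphs at temperatures uniform on [t_low, t_high].

    Split sizes (train, val, test) must sum to n_sims; since labels are i.i.d.
    uniform draws, a positional split is already random. Fully determined by
    the seed: per-simulation seeds are spawned from one SeedSequence.
    """
    if sum(split_sizes) != n_sims:
        raise ConfigError(f"split sizes {split_sizes} do not sum to n_sims={n_sims}")
    if isinstance(preset, str):
        preset = PRESETS[preset]
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    labels = rng.uniform(t_low, t_high, size=n_sims)
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]
    graphs = []
    for T, s in zip(labels, sim_seeds):
        conn = ising_connectivity(preset.config(float(T), s), preset.block_size, preset.target_n)
        graphs.append(knn_graph(conn, k, rank_by))
    split = np.repeat(["train", "val", "test"], split_sizes)
    return LabeledGraphDataset(
        graphs,
        labels,
        split,
        seed,
        preset.name,
        k,
        {"t_low": t_low, "t_high": t_high, "rank_by": rank_by, "sim_seeds": sim_seeds},
    )


def save_dataset(dataset: LabeledGraphDataset, outdir: str | Path) -> Path:
    """Graph-per-file layout with a delimited manifest for partial regeneration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, g in enumerate(dataset.graphs):
        path = f"graph_{i:05d}.npz"
        np.savez_compressed(outdir / path, features=g.node_features, edges=g.edges, k=g.k)
        rows.append((i, path, dataset.labels[i], dataset.split[i], dataset.seed))
    pd.DataFrame(rows, columns=["graph_id", "path", "temperature", "split", "seed"]).to_csv(
        outdir / "manifest.csv", index=False
    )
    (outdir / "meta.json").write_text(
        json.dumps({"preset": dataset.preset, "k": dataset.k, **dataset.meta})
    )
    return outdir


def load_dataset(indir: str | Path) -> LabeledGraphDataset:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    meta = json.loads((indir / "meta.json").read_text())
    graphs = []
    for path in manifest["path"]:
        z = np.load(indir / path)
        graphs.append(ROIGraph(z["features"], z["edges"], int(z["k"])))
    return LabeledGraphDataset(
        graphs,
        manifest["temperature"].to_numpy(),
        manifest["split"].to_numpy(),
        int(manifest["seed"].iloc[0]),
        meta.pop("preset", "full"),
        meta.pop("k", 10),
        meta,
    )
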