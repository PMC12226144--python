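"""Apply a trained regressor to connectivity data and express results vs. criticality.

Empirical inputs enter either as an ROI x time table of regional signals
(Pearson-correlated here) or as a precomputed N x N connectivity matrix. The
graph is built with the same neighbour count the model was trained with, the
regressor runs in evaluation mode, and the estimate is reported both raw and
relative to the exact critical temperature T_c = 2/ln(1+sqrt(2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coarse_grain import pearson_connectivity
from .errors import ShapeError
from .gcn import TrainedRegressor, predict
from .graph_build import knn_graph
from .ising_sim import critical_temperature

__all__ = ["TemperatureEstimate", "estimate_temperature", "roi_connectivity", "estimate_many"]


@dataclass
class TemperatureEstimate:
    """An estimated control parameter and its distance from the critical point."""

    T_hat: float
    delta: float      # T_hat - T_c
    abs_delta: float  # |T_hat - T_c|
    model_id: str
    subject_id: str | None = None


def roi_connectivity(timeseries: np.ndarray, expected_rois: int | None = 333) -> np.ndarray:
    """Pearson connectivity of an (n_roi, n_time) regional-signal table.

    A row count different from the configured parcellation size only warns;
    the hard dimensionality gate sits at estimate_temperature.
    """
    ts = np.asarray(timeseries, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("time series must be 2D with >= 2 time points")
    if expected_rois is not None and ts.shape[0] != expected_rois:
        warnings.warn(
            f"{ts.shape[0]} ROIs differs from the configured parcellation size {expected_rois}",
            stacklevel=2,
        )
    return pearson_connectivity(ts)


def estimate_temperature(
    conn: np.ndarray,
    model: TrainedRegressor,
    k: int | None = None,
    subject_id: str | None = None,
) -> TemperatureEstimate:
    """kNN graph -> evaluation-mode forward pass -> distance from T_c."""
    conn = np.asarray(conn, dtype=np.float64)
    n = conn.shape[0]
    if conn.ndim != 2 or conn.shape[1] != n or n != model.n_nodes:
        raise ShapeError(
            f"connectivity is {conn.shape} but the model expects "
            f"({model.n_nodes}, {model.n_nodes})"
        )
    if k is None:
        k = model.k
    elif k != model.k:
        warnings.warn(
            f"k={k} differs from the training value k={model.k}; estimates may be biased",
            stacklevel=2,
        )
    graph = knn_graph(conn, k)
    t_hat = float(predict(model, [graph])[0])
    delta = t_hat - critical_temperature()
    return TemperatureEstimate(t_hat, delta, abs(delta), model.model_id(), subject_id)


def estimate_many(
    matrices: dict[str, np.ndarray],
    model: TrainedRegressor,
    k: int | None = None,
) -> pd.DataFrame:
    """Batch estimation; failed subjects are logged as warnings and skipped."""
    rows = []
    for sid, conn in matrices.items():
        try:
            est = estimate_temperature(conn, model, k, subject_id=sid)
        except Exception as exc:  # noqa: BLE001 - batch mode must not die mid-cohort
            warnings.warn(f"subject {sid} skipped: {exc}", stacklevel=2)
            continue
        rows.append((sid, est.T_hat, est.delta, est.abs_delta, est.model_id))
    return pd.DataFrame(rows, columns=["subject_id", "T_hat", "delta", "abs_delta", "model_id"])
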