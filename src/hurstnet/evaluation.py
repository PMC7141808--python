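"""Estimator accuracy metrics on labeled fBm test sets.

For a test ensemble with true exponents ``H_sim`` and estimates ``H_est``:

* ``sigma_h``  — mean absolute error, mean |H_sim - H_est|
* ``delta_h``  — per-track differences H_sim - H_est
* per-H-bin bias ``b = E[H_est] - H_sim``, variance of H_est, and
  MSE, which decomposes exactly as ``MSE = Var + b^2`` per bin.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .errors import ParameterError
from .network import TrainedModel, estimate_hurst_many
from .trajectory import Trajectory

__all__ = ["EstimatorReport", "evaluate", "evaluate_estimates"]


@dataclass
class EstimatorReport:
    """Accuracy summary of one estimator on one labeled test set."""

    sigma_h: float
    delta_h_samples: np.ndarray
    bin_centers: np.ndarray
    bias_by_h: np.ndarray
    variance_by_h: np.ndarray
    mse_by_h: np.ndarray
    n: int

    def max_decomposition_error(self) -> float:
        """Worst-bin violation of MSE = Var + bias^2 (float noise only)."""
        good = ~np.isnan(self.mse_by_h)
        return float(
            np.max(
                np.abs(
                    self.mse_by_h[good]
                    - (self.variance_by_h[good] + self.bias_by_h[good] ** 2)
                )
            )
        )


def evaluate_estimates(
    h_true: np.ndarray, h_est: np.ndarray, n_bins: int = 20
) -> EstimatorReport:
    """Build an :class:`EstimatorReport` from paired true/estimated H."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    if h_true.size == 0:
        raise ParameterError("empty test set")
    if h_true.shape != h_est.shape:
        raise ParameterError("h_true and h_est must have the same shape")
    good = np.isfinite(h_est)
    h_true, h_est = h_true[good], h_est[good]
    if h_true.size == 0:
        raise ParameterError("no finite estimates")
    delta = h_true - h_est
    sigma_h = float(np.mean(np.abs(delta)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bias = np.full(n_bins, np.nan)
    var = np.full(n_bins, np.nan)
    mse = np.full(n_bins, np.nan)
    which = np.clip(np.digitize(h_true, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        err = (h_est - h_true)[which == b]
        if err.size:
            bias[b] = err.mean()
            var[b] = np.mean((err - err.mean()) ** 2)
            mse[b] = np.mean(err * err)
    return EstimatorReport(sigma_h, delta, centers, bias, var, mse, n=h_true.size)


def evaluate(
    estimator: Union[TrainedModel, Callable[[Trajectory], float]],
    test_set: Sequence,
    n_bins: int = 20,
) -> EstimatorReport:
    """Evaluate a trained model or a per-track callable on (track, H) pairs.

    ``test_set`` items may be ``(Trajectory, h)`` pairs or objects with
    ``trajectory`` / ``true_hurst_series`` attributes (constant-H labels).
    """
    pairs = []
    for item in test_set:
        if hasattr(item, "trajectory"):
            pairs.append((item.trajectory, float(np.median(item.true_hurst_series))))
        else:
            traj, h = item
            pairs.append((traj, float(h)))
    if not pairs:
        raise ParameterError("empty test set")
    h_true = np.array([h for _, h in pairs])
    if isinstance(estimator, TrainedModel):
        if any(t.n_dim != 1 for t, _ in pairs):
            h_est = np.array(
                [
                    np.mean(
                        [
                            estimate_hurst_many(estimator, t.coordinate(a)[None, :])[0]
                            for a in range(t.n_dim)
                        ]
                    )
                    for t, _ in pairs
                ]
            )
        else:
            windows = np.stack([t.coordinate(0) for t, _ in pairs])
            h_est = estimate_hurst_many(estimator, windows)
    else:
        h_est = np.empty(len(pairs))
        for i, (traj, _) in enumerate(pairs):
            try:
                h_est[i] = estimator(traj)
            except Exception:
                h_est[i] = np.nan
    return evaluate_estimates(h_true, h_est, n_bins=n_bins)
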