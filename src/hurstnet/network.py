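"""Dense feedforward Hurst-exponent regressor.

A small fully connected network maps a differenced, range-normalized
position window of ``n`` points to an estimate of the Hurst exponent.  All
nodes, including the single output node, use ReLU activations, and the
parameters are optimized with RMSprop on a mean-squared-error loss; the
training set is freshly simulated fBm with H drawn uniformly on (0, 1).

Three layer layouts are supported.  With ``n`` input points and ``L``
hidden layers the total node counts are

* triangular:       sum_{l=0..L} (n - l) + 1   (widths shrink by one per layer)
* rectangular:      n * L + 1                  (hidden widths all n)
* anti-triangular:  sum_{l=0..L} (n + l) + 1   (widths grow by one per layer)

where the count includes the input layer (width ``n`` in the formulas) and
the output node.  Because differencing ``n`` points yields ``n - 1``
values, the realized input width is ``n - 1`` and hidden widths follow the
same progression from there.

Preprocessing is scale- and shift-invariant: the network sees
``(x_{i+1} - x_i) / (max(x) - min(x))``, so the diffusion coefficient and
the spatial units of a track do not matter.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import fbm
from .errors import (
    DegenerateInputError,
    ModelFormatError,
    ParameterError,
    TrainingError,
)

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedModel",
    "node_count",
    "layer_widths",
    "preprocess",
    "build_network",
    "train",
    "estimate_hurst",
    "estimate_hurst_many",
    "estimate_hurst_subsampled",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1
_STRUCTURES = ("triangular", "rectangular", "anti_triangular")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``n_input`` is the window length in *points*; the network consumes the
    ``n_input - 1`` consecutive differences.
    """

    structure: str = "triangular"
    n_input: int = 100
    n_hidden_layers: int = 3
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ParameterError(f"structure must be one of {_STRUCTURES}")
        if self.n_input < 3:
            raise ParameterError("n_input must be >= 3 points")
        if self.n_hidden_layers < 1:
            raise ParameterError("need at least one hidden layer")
        if self.activation != "relu":
            raise ParameterError("only ReLU activation is supported")
        if self.structure == "triangular" and self.n_hidden_layers >= self.n_input - 1:
            raise ParameterError(
                "triangular structure needs fewer hidden layers than input width"
            )


def node_count(spec: NetworkSpec) -> int:
    """Total node count of the architecture family.

    Triangular and anti-triangular counts include the input layer (width
    ``n``) plus the output node; the rectangular count is the hidden plus
    output nodes, ``n L + 1``.
    """
    n, L = spec.n_input, spec.n_hidden_layers
    if spec.structure == "triangular":
        return sum(n - l for l in range(L + 1)) + 1
    if spec.structure == "anti_triangular":
        return sum(n + l for l in range(L + 1)) + 1
    return n * L + 1


def layer_widths(spec: NetworkSpec) -> List[int]:
    """Realized widths ``[input, hidden..., output]`` (input = n - 1 diffs)."""
    d = spec.n_input - 1
    L = spec.n_hidden_layers
    if spec.structure == "triangular":
        hidden = [d - l for l in range(1, L + 1)]
    elif spec.structure == "anti_triangular":
        hidden = [d + l for l in range(1, L + 1)]
    else:
        hidden = [d] * L
    if any(w < 1 for w in hidden):
        raise ParameterError("architecture collapses to zero-width layer")
    return [d] + hidden + [1]


def preprocess(series: np.ndarray) -> np.ndarray:
    """Difference and range-normalize a position window.

    ``[x_0..x_{n-1}] -> [(x_1-x_0)/range(x), ..., (x_{n-1}-x_{n-2})/range(x)]``

    Invariant under any affine map ``x -> a x + b`` with ``a > 0``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("preprocess expects a 1D series of >= 2 points")
    rng_x = x.max() - x.min()
    if rng_x == 0:
        raise DegenerateInputError("constant window has zero range")
    return np.diff(x) / rng_x


def preprocess_batch(windows: np.ndarray) -> np.ndarray:
    """Row-wise :func:`preprocess`; rows with zero range come back as NaN."""
    rng_x = windows.max(axis=1) - windows.min(axis=1)
    out = np.diff(windows, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out /= rng_x[:, None]
    out[rng_x == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# network internals


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class _Dense:
    """One densely connected layer with its RMSprop state."""

    def __init__(self, w: np.ndarray, b: np.ndarray):
        self.w = w
        self.b = b
        self.sw = np.zeros_like(w)
        self.sb = np.zeros_like(b)


def _init_layers(widths: Sequence[int], rng: np.random.Generator) -> List[_Dense]:
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(fan_out)
        layers.append(_Dense(w, b))
    # positive output bias keeps the ReLU output node alive at init
    layers[-1].b[:] = 0.5
    return layers


def _forward(layers: List[_Dense], x: np.ndarray) -> np.ndarray:
    a = x
    for layer in layers:
        a = _relu(a @ layer.w + layer.b)
    return a[:, 0]


def _train_step(
    layers: List[_Dense], x: np.ndarray, y: np.ndarray, lr: float, rho: float, eps: float
) -> float:
    """One RMSprop step on an MSE batch; returns the batch loss."""
    acts = [x]
    a = x
    for layer in layers:
        a = _relu(a @ layer.w + layer.b)
        acts.append(a)
    pred = acts[-1][:, 0]
    err = pred - y
    loss = float(np.mean(err * err))
    m = x.shape[0]
    delta = (2.0 / m) * err[:, None] * (acts[-1] > 0)
    for i in range(len(layers) - 1, -1, -1):
        layer = layers[i]
        gw = acts[i].T @ delta
        gb = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ layer.w.T) * (acts[i] > 0)
        layer.sw = rho * layer.sw + (1.0 - rho) * gw * gw
        layer.sb = rho * layer.sb + (1.0 - rho) * gb * gb
        layer.w -= lr * gw / (np.sqrt(layer.sw) + eps)
        layer.b -= lr * gb / (np.sqrt(layer.sb) + eps)
    return loss


@dataclass
class TrainingConfig:
    """Training-run settings.

    The defaults regress H on freshly simulated constant-H fBm windows of
    ``spec.n_input`` points; set ``subsample_from`` to train on windows of
    ``subsample_from`` points from which ``spec.n_input`` random time points
    are retained (intermittent-detection variant).
    """

    n_train: int = 200_000
    n_val: int = 10_000
    batch_size: int = 128
    max_epochs: int = 40
    learning_rate: float = 1e-3
    rho: float = 0.9
    eps: float = 1e-8
    patience: int = 4
    subsample_from: Optional[int] = None
    noise_nsr_max: float = 0.0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ParameterError("n_train and n_val must be positive")
        if self.subsample_from is not None and self.subsample_from < 2:
            raise ParameterError("subsample_from must be >= 2")
        if self.noise_nsr_max < 0:
            raise ParameterError("noise_nsr_max must be >= 0")


@dataclass
class TrainedModel:
    """A fitted regression network plus its provenance."""

    spec: NetworkSpec
    layers: List[_Dense]
    training_config: TrainingConfig
    seed: Optional[int]
    val_mae: float = np.nan
    loss_history: List[float] = field(default_factory=list)
    provenance: str = f"hurstnet-model-v{_FORMAT_VERSION}"

    @property
    def n_input(self) -> int:
        return self.spec.n_input

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Forward pass on preprocessed feature rows, clamped to [0, 1]."""
        feats = np.atleast_2d(np.asarray(features, dtype=float))
        if feats.shape[1] != self.spec.n_input - 1:
            raise ParameterError(
                f"model expects {self.spec.n_input - 1} features, got {feats.shape[1]}"
            )
        out = np.empty(feats.shape[0])
        for lo in range(0, feats.shape[0], 65536):
            hi = min(lo + 65536, feats.shape[0])
            out[lo:hi] = _forward(self.layers, feats[lo:hi])
        return np.clip(out, 0.0, 1.0)


def build_network(spec: NetworkSpec, seed: Optional[int] = None) -> TrainedModel:
    """Construct an untrained (randomly initialized) model."""
    rng = np.random.default_rng(seed)
    layers = _init_layers(layer_widths(spec), rng)
    return TrainedModel(spec, layers, TrainingConfig(), seed)


def make_training_windows(
    n_samples: int,
    n_points: int,
    rng: np.random.Generator,
    subsample_from: Optional[int] = None,
    noise_nsr_max: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate fBm windows with H ~ U(0,1) and return (features, H).

    Features are the differenced, range-normalized windows.  With
    ``subsample_from = N`` the windows are N-point tracks from which
    ``n_points`` random time points are retained before preprocessing
    (time stamps of the retained points are discarded).  A positive
    ``noise_nsr_max`` corrupts each window with Gaussian measurement noise
    of strength NSR ~ U(0, noise_nsr_max) — augmentation that trades a
    little clean accuracy for robustness on noisy experimental tracks.
    """
    h = rng.uniform(0.0, 1.0, size=n_samples)
    h = np.clip(h, 1e-4, 1.0 - 1e-4)
    n_full = subsample_from if subsample_from is not None else n_points
    pos = fbm.simulate_fbm_ensemble(h, n_full, rng=rng)
    if subsample_from is not None:
        idx = fbm.subsample_indices(n_full, n_points, rng, m=n_samples)
        pos = np.take_along_axis(pos, idx, axis=1)
    if noise_nsr_max > 0:
        nsr = rng.uniform(0.0, noise_nsr_max, n_samples)[:, None]
        pos = pos + rng.standard_normal(pos.shape) * (nsr * pos.std(axis=1, keepdims=True))
    feats = preprocess_batch(pos)
    good = ~np.isnan(feats).any(axis=1)
    return feats[good], h[good]


def train(
    spec: NetworkSpec,
    config: Optional[TrainingConfig] = None,
    seed: Optional[int] = None,
) -> TrainedModel:
    """Train a Hurst regressor on freshly simulated fBm windows.

    Early stopping monitors validation MAE with the configured patience and
    the best-epoch weights are restored.  Deterministic for a fixed
    (spec, config, seed) in a single-threaded run.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    layers = _init_layers(layer_widths(spec), rng)

    x_train, y_train = make_training_windows(
        config.n_train, spec.n_input, rng, config.subsample_from, config.noise_nsr_max
    )
    x_val, y_val = make_training_windows(
        config.n_val, spec.n_input, rng, config.subsample_from, config.noise_nsr_max
    )

    best_mae = np.inf
    best_weights = None
    bad_epochs = 0
    history: List[float] = []
    m = x_train.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, m, config.batch_size):
            sel = order[lo : lo + config.batch_size]
            loss = _train_step(
                layers, x_train[sel], y_train[sel], config.learning_rate, config.rho, config.eps
            )
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= n_batches
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        history.append(epoch_loss)
        val_pred = np.clip(_forward(layers, x_val), 0.0, 1.0)
        val_mae = float(np.mean(np.abs(val_pred - y_val)))
        if val_mae < best_mae - 1e-5:
            best_mae = val_mae
            best_weights = [(l.w.copy(), l.b.copy()) for l in layers]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_weights is not None:
        for layer, (w, b) in zip(layers, best_weights):
            layer.w, layer.b = w, b
    return TrainedModel(spec, layers, config, seed, val_mae=best_mae, loss_history=history)


def estimate_hurst(model: TrainedModel, series: np.ndarray) -> float:
    """Estimate H for one window of exactly ``model.n_input`` points."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size != model.n_input:
        raise ParameterError(f"series must have exactly {model.n_input} points")
    return float(model.predict(preprocess(x)[None, :])[0])


def estimate_hurst_many(model: TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Vectorized estimates for rows of position windows.

    Rows with zero range (constant windows) yield NaN rather than raising.
    """
    w = np.atleast_2d(np.asarray(windows, dtype=float))
    if w.shape[1] != model.n_input:
        raise ParameterError(f"windows must have {model.n_input} columns")
    feats = preprocess_batch(w)
    out = np.full(w.shape[0], np.nan)
    good = ~np.isnan(feats).any(axis=1)
    if good.any():
        out[good] = model.predict(feats[good])
    return out


def estimate_hurst_subsampled(
    model_bank: dict, sampled_series: np.ndarray, n_rand: int
) -> float:
    """Estimate H from ``n_rand`` retained points using a bank of per-size
    models; gaps are ignored (differences of retained values only)."""
    if n_rand not in model_bank:
        raise ParameterError(f"no model trained for input size {n_rand}")
    x = np.asarray(sampled_series, dtype=float)
    if x.size != n_rand:
        raise ParameterError(f"expected {n_rand} retained points, got {x.size}")
    return estimate_hurst(model_bank[n_rand], x)


# ---------------------------------------------------------------------------
# persistence

_N_PROBE = 16


def _probe_features(spec: NetworkSpec) -> np.ndarray:
    """Fixed pseudo-random feature rows used to fingerprint a model."""
    rng = np.random.default_rng(1234567)
    return rng.standard_normal((_N_PROBE, spec.n_input - 1)) * 0.1


def save_model(model: TrainedModel, path) -> None:
    """Serialize to a self-describing container (architecture JSON + weights
    + probe predictions for integrity verification on load)."""
    arch = {
        "format_version": _FORMAT_VERSION,
        "structure": model.spec.structure,
        "n_input": model.spec.n_input,
        "n_hidden_layers": model.spec.n_hidden_layers,
        "activation": model.spec.activation,
        "seed": model.seed,
        "val_mae": None if np.isnan(model.val_mae) else model.val_mae,
        "provenance": model.provenance,
    }
    probe = model.predict(_probe_features(model.spec))
    arrays = {"probe": probe}
    for i, layer in enumerate(model.layers):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    np.savez(path, arch=json.dumps(arch), **arrays)


def load_model(path) -> TrainedModel:
    """Load a saved model; verifies format version and probe predictions."""
    try:
        data = np.load(path, allow_pickle=False)
        arch = json.loads(str(data["arch"]))
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path!r}: {exc}") from exc
    if arch.get("format_version") != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {arch.get('format_version')!r}"
        )
    spec = NetworkSpec(
        structure=arch["structure"],
        n_input=arch["n_input"],
        n_hidden_layers=arch["n_hidden_layers"],
        activation=arch["activation"],
    )
    widths = layer_widths(spec)
    layers = []
    for i in range(len(widths) - 1):
        if f"w{i}" not in data or f"b{i}" not in data:
            raise ModelFormatError("model file is missing weight arrays")
        w, b = data[f"w{i}"], data[f"b{i}"]
        if w.shape != (widths[i], widths[i + 1]) or b.shape != (widths[i + 1],):
            raise ModelFormatError("weight shapes do not match the declared spec")
        layers.append(_Dense(w.copy(), b.copy()))
    model = TrainedModel(
        spec,
        layers,
        TrainingConfig(),
        arch.get("seed"),
        val_mae=arch["val_mae"] if arch.get("val_mae") is not None else np.nan,
        provenance=arch.get("provenance", ""),
    )
    probe = model.predict(_probe_features(spec))
    if not np.array_equal(probe, data["probe"]):
        raise ModelFormatError("probe predictions do not match stored checksum")
    return model
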