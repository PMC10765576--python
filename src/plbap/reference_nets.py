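"""Deterministic reference forward passes and declarative architecture configs.

This module provides the numerical cores of the four model families as
backend-free computations:

* the atomistic dense head that maps each row of a pooled environment
  tensor to an atomic energy and sums them into a molecular energy;
* the binding thermodynamic cycle  dG = E_complex - E_protein - E_ligand;
* the spectral graph-convolution propagation
  H' = act(L H Theta), L = D^{-1/2} (A + I) D^{-1/2};
* a generic message-passing step with a permutation-invariant readout.

Full training at benchmark scale is out of scope; a thin ``fit`` interface
backed by scikit-learn estimators supports small learnability checks.  The
printed layer/filter configurations of the reference architectures are kept
as declarative :class:`ArchitectureConfig` objects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .acnn_featurizer import PooledEnvTensor
from .complex_model import ValidationError

__all__ = [
    "AtomisticHeadWeights",
    "ArchitectureConfig",
    "atomistic_energy",
    "thermodynamic_delta",
    "gcn_propagate",
    "message_passing_step",
    "readout",
    "onionnet_architecture",
    "kdeep_architecture",
    "graphbar_architecture",
    "acnn_architecture",
    "onionnet_loss",
    "fit",
]

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
}


def _activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValidationError(f"unknown activation {name!r}") from None


@dataclass
class AtomisticHeadWeights:
    """Per-layer (weight, bias) pairs of the shared atomistic dense stack."""

    layers: list[tuple[np.ndarray, np.ndarray]]
    activation: str = "relu"

    def __post_init__(self) -> None:
        for (w1, _), (w2, _) in zip(self.layers, self.layers[1:]):
            if w1.shape[1] != w2.shape[0]:
                raise ValidationError(
                    f"incompatible layer dims {w1.shape} -> {w2.shape}")

    @classmethod
    def random(cls, input_dim: int, hidden: Sequence[int] = (32, 32, 16),
               activation: str = "relu", seed: int = 0) -> "AtomisticHeadWeights":
        rng = np.random.default_rng(seed)
        dims = [input_dim, *hidden, 1]
        layers = [(rng.normal(0, 1 / np.sqrt(a), size=(a, b)), np.zeros(b))
                  for a, b in zip(dims, dims[1:])]
        return cls(layers=layers, activation=activation)


def atomistic_energy(pooled: PooledEnvTensor,
                     weights: AtomisticHeadWeights) -> tuple[np.ndarray, float]:
    """Per-atom energies and their sum.

    Each atom's flattened K*Q pooled row passes through the shared dense
    stack (activation after every layer but the last); the molecular energy
    is the sum of the per-atom outputs, hence invariant to atom order.
    """
    values = pooled.values
    h = values.reshape(values.shape[0], -1)
    first_w = weights.layers[0][0]
    if h.shape[1] != first_w.shape[0]:
        raise ValidationError(
            f"pooled row dim {h.shape[1]} does not match head input {first_w.shape[0]}")
    act = _activation(weights.activation)
    for w, b in weights.layers[:-1]:
        h = act(h @ w + b)
    w, b = weights.layers[-1]
    energies = (h @ w + b).ravel()
    return energies, float(energies.sum())


def thermodynamic_delta(e_complex: float, e_protein: float,
                        e_ligand: float) -> float:
    """Binding free-energy estimate dG = E_complex - E_protein - E_ligand."""
    for e in (e_complex, e_protein, e_ligand):
        if not np.isfinite(e):
            raise ValidationError("energies must be finite")
    return e_complex - e_protein - e_ligand


def gcn_propagate(node_features: np.ndarray, adjacency_slice: np.ndarray,
                  theta: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One spectral graph-convolution layer: act(L H Theta) with the
    renormalized Laplacian L = D^{-1/2}(A + I)D^{-1/2}, D_ii = sum_j (A+I)_ij.

    Padded nodes (zero adjacency, zero features) get degree 1 from the
    self-loop and propagate zero rows.
    """
    h = np.asarray(node_features, float)
    a = np.asarray(adjacency_slice, float)
    if a.shape[0] != a.shape[1] or a.shape[0] != h.shape[0]:
        raise ValidationError("adjacency and node features must share the node axis")
    if h.shape[1] != theta.shape[0]:
        raise ValidationError("theta rows must match feature columns")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    laplacian = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return _activation(activation)(laplacian @ h @ theta)


def message_passing_step(node_features: np.ndarray, adjacency_slice: np.ndarray,
                         message_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
                         update_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
                         ) -> np.ndarray:
    """Generic message-passing update.

    r_i = sum over neighbors j of message_fn(h_i, h_j); h_i' = update_fn(h_i, r_i).
    ``message_fn`` and ``update_fn`` are pure functions of feature vectors.
    """
    h = np.asarray(node_features, float)
    a = np.asarray(adjacency_slice, float)
    n = h.shape[0]
    messages = np.zeros_like(h)
    for i in range(n):
        neighbors = np.flatnonzero(a[i] != 0)
        for j in neighbors:
            messages[i] = messages[i] + message_fn(h[i], h[j])
    return np.stack([update_fn(h[i], messages[i]) for i in range(n)])


def readout(node_features: np.ndarray, mode: str = "sum",
            mask: np.ndarray | None = None) -> np.ndarray:
    """Permutation-invariant graph readout (sum or mean over real nodes)."""
    h = np.asarray(node_features, float)
    if mask is not None:
        h = h[np.asarray(mask, bool)]
    if mode == "sum":
        return h.sum(axis=0)
    if mode == "mean":
        return h.mean(axis=0)
    raise ValidationError(f"unknown readout mode {mode!r}")


# ---------------------------------------------------------------------------
# declarative architecture configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureConfig:
    """A flat, declarative record of a reference architecture (layer kinds
    and the published filter/unit counts); not an executable network."""

    name: str
    entries: dict[str, object] = field(default_factory=dict)

    def to_flat_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"name = {self.name}\n")
            for key, value in sorted(self.entries.items()):
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_flat_file(cls, path) -> "ArchitectureConfig":
        entries: dict[str, object] = {}
        name = "unnamed"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "name":
                    name = value
                    continue
                try:
                    entries[key] = int(value)
                except ValueError:
                    try:
                        entries[key] = float(value)
                    except ValueError:
                        entries[key] = value
        return cls(name=name, entries=entries)


def acnn_architecture() -> ArchitectureConfig:
    """Atomistic head sizes of the reference atomic-convolution model."""
    return ArchitectureConfig("acnn", {
        "dense_units_1": 32, "dense_units_2": 32, "dense_units_3": 16,
        "output_units": 1,
    })


def onionnet_architecture() -> ArchitectureConfig:
    """2D-CNN over contact matrices: 3 conv layers (4x4 kernels, stride 1)
    with 16/64/128 filters, then dense layers of 400/200/100 units."""
    return ArchitectureConfig("onionnet_2dcnn", {
        "conv_filters_1": 16, "conv_filters_2": 64, "conv_filters_3": 128,
        "conv_kernel": 4, "conv_stride": 1,
        "dense_units_1": 400, "dense_units_2": 200, "dense_units_3": 100,
    })


def kdeep_architecture() -> ArchitectureConfig:
    """SqueezeNet-style 3D-CNN: an initial 7x7x7 stride-2 convolution and
    fire modules (squeeze n, expand 4n + 4n); Fire2 squeezes to 16."""
    return ArchitectureConfig("kdeep_squeezenet", {
        "stem_kernel": 7, "stem_stride": 2,
        "fire2_squeeze": 16, "fire2_expand_1x1": 64, "fire2_expand_3x3": 64,
        "pool_kernel": 3, "pool_stride": 2,
    })


def graphbar_architecture(n_edge_types: int = 3,
                          aggregator: str = "sum") -> ArchitectureConfig:
    """Spectral-GCN blocks per edge type: conv 128/128/32, dense
    128/128/16*N_et, dropout 0.5; block readouts aggregated (sum by
    default) and concatenated into a final 128-unit dense layer."""
    return ArchitectureConfig("graphbar", {
        "n_edge_types": n_edge_types,
        "preprocess_dense_units": 128,
        "conv_filters_1": 128, "conv_filters_2": 128, "conv_filters_3": 32,
        "dense_units_1": 128, "dense_units_2": 128,
        "dense_units_3": 16 * n_edge_types,
        "dropout": 0.5, "block_aggregator": aggregator,
        "final_dense_units": 128,
    })


# ---------------------------------------------------------------------------
# pluggable training backend
# ---------------------------------------------------------------------------

def onionnet_loss(y_true: np.ndarray, y_pred: np.ndarray,
                  alpha: float = 0.7, beta: float = 0.3) -> float:
    """Composite loss alpha*(1 - PC) + beta*RMSE combining correlation and
    error; the published description names both terms without a formula,
    so the weights are configurable."""
    from .evaluation import pearson, rmse

    return alpha * (1.0 - pearson(y_true, y_pred)) + beta * rmse(y_true, y_pred)


def fit(features: np.ndarray, labels: np.ndarray, config: str = "linear",
        seed: int = 0):
    """Fit a small regression model on flattened features.

    ``config="linear"`` uses ridge regression; ``config="mlp"`` a two-layer
    perceptron.  Returns an object with a ``predict(features)`` method.
    This is a learnability hook, not a benchmark trainer.
    """
    from sklearn.linear_model import Ridge
    from sklearn.neural_network import MLPRegressor

    x = np.asarray(features, float).reshape(len(features), -1)
    y = np.asarray(labels, float)
    if config == "linear":
        model = Ridge(alpha=1e-6)
    elif config == "mlp":
        model = MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=2000,
                             random_state=seed)
    else:
        raise ValidationError(f"unknown fit config {config!r}")
    model.fit(x, y)

    class _Fitted:
        def __init__(self, est):
            self._est = est

        def predict(self, feats: np.ndarray) -> np.ndarray:
            return self._est.predict(
                np.asarray(feats, float).reshape(len(feats), -1))

    return _Fitted(model)
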