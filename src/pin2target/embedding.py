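"""Symmetric deep autoencoder over binary adjacency rows.

A plain NumPy multilayer perceptron: ReLU on every hidden layer, sigmoid on
the output, binary cross-entropy reconstruction loss, Adam updates. The
decoder mirrors the encoder layer sizes. The middle (narrowest) layer's
activations are the latent features used downstream.

Two configuration profiles exist: ``paper`` (lr 1e-6, 10,000 epochs, batch
10 — the full-scale reference settings) and ``desk`` (lr 1e-3, 200 epochs)
for reduced-scale runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pin2target.pin_data import AdjacencyMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-7  # probability clipping inside BCE to avoid log(0)


@dataclass
class AutoencoderConfig:
    """Encoder layer sizes (input first, latent last) plus optimizer knobs."""

    layer_sizes: list[int]
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = list(self.layer_sizes)
        if len(sizes) < 2:
            raise ValueError("need at least an input and a latent layer")
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"encoder sizes must be strictly decreasing: {sizes}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def profile(
        cls, name: str, layer_sizes: list[int], seed: int = 0
    ) -> "AutoencoderConfig":
        if name == "paper":
            return cls(layer_sizes, learning_rate=1e-6, epochs=10_000,
                       batch_size=10, seed=seed)
        if name == "desk":
            return cls(layer_sizes, learning_rate=1e-3, epochs=200,
                       batch_size=10, seed=seed)
        raise ValueError(f"unknown profile {name!r} (expected 'paper' or 'desk')")


def make_layer_pyramid(
    n_input: int, d_latent: int = 100, n_layers: int = 7
) -> list[int]:
    """Encoder size list from input width down to the latent width.

    The full-scale architecture (6338 -> 100 over 7 layers) is returned
    verbatim; other shapes interpolate geometrically between the endpoints.
    """
    if d_latent >= n_input:
        raise ValueError(f"d_latent ({d_latent}) must be < n_input ({n_input})")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if (n_input, d_latent, n_layers) == (6338, 100, 7):
        return [6338, 3000, 1500, 500, 250, 150, 100]
    ratio = (d_latent / n_input) ** (1.0 / (n_layers - 1))
    sizes = [n_input]
    for i in range(1, n_layers - 1):
        sizes.append(int(round(n_input * ratio**i)))
    sizes.append(d_latent)
    # enforce strict decrease after rounding
    for i in range(1, len(sizes)):
        if sizes[i] >= sizes[i - 1]:
            sizes[i] = sizes[i - 1] - 1
    if sizes[-1] < d_latent:
        raise ValueError(
            f"cannot build {n_layers} strictly decreasing layers from "
            f"{n_input} to {d_latent}"
        )
    return sizes


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean BCE over all entries with probability clipping."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class AutoencoderModel:
    """Trained weights for the full encoder+decoder stack.

    ``sizes`` is the complete stack (encoder sizes followed by the mirrored
    decoder tail); ``latent_index`` marks the layer whose activations are
    the embedding.
    """

    sizes: list[int]
    latent_index: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.sizes[0]

    @property
    def d_latent(self) -> int:
        return self.sizes[self.latent_index]

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = _sigmoid(z) if i == last else _relu(z)
            acts.append(h)
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        for i in range(self.latent_index):
            h = _relu(h @ self.weights[i] + self.biases[i])
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[-1]


def train_autoencoder(
    adjacency: AdjacencyMatrix, config: AutoencoderConfig
) -> AutoencoderModel:
    """Minimize reconstruction BCE over adjacency rows with Adam.

    Rows are shuffled each epoch with the run seed; the per-epoch trace
    records the mean minibatch loss. Raises on non-binary input or a
    non-finite loss.
    """
    x = np.asarray(adjacency.entries, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("autoencoder input must be binary")
    enc = list(config.layer_sizes)
    if enc[0] != x.shape[1]:
        raise ValueError(
            f"encoder input width {enc[0]} does not match matrix width {x.shape[1]}"
        )
    sizes = enc + enc[-2::-1]  # mirrored decoder
    rng = np.random.default_rng(config.seed)

    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    model = AutoencoderModel(sizes, len(enc) - 1, weights, biases)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    step = 0
    n = x.shape[0]
    last = len(weights) - 1

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            xb = x[order[start : start + config.batch_size]]
            acts = model._forward(xb)
            p = np.clip(acts[-1], _EPS, 1.0 - _EPS)
            loss = binary_cross_entropy(xb, p)
            batch_losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            # backprop: mean-over-entries BCE with sigmoid output
            delta = (p - xb) / (xb.shape[0] * xb.shape[1])
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - beta2**step) / (1 - beta1**step)
            )
            for i in range(last, -1, -1):
                gw = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0)
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw**2
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb**2
                weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + eps)
                biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + eps)
        model.loss_trace.append(float(np.mean(batch_losses)))
    logger.info(
        "autoencoder trained: %d epochs, loss %.5f -> %.5f",
        config.epochs, model.loss_trace[0], model.loss_trace[-1],
    )
    return model


@dataclass
class LatentFeatureMatrix:
    """N x d middle-layer activations aligned to the gene order, with
    zero-variance dimensions flagged (kept in the matrix)."""

    values: np.ndarray
    genes: list[str]
    zero_variance_dims: list[int]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(
            self.values,
            index=self.genes,
            columns=[f"dim_{i + 1}" for i in range(self.d)],
        )
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.8g")


def encode(model: AutoencoderModel, adjacency: AdjacencyMatrix) -> LatentFeatureMatrix:
    """Middle-layer activations per gene; flags all-constant dimensions."""
    x = np.asarray(adjacency.entries, dtype=float)
    if x.shape[1] != model.n_input:
        raise ValueError(
            f"matrix width {x.shape[1]} does not match model input {model.n_input}"
        )
    z = model.encode(x)
    flat = [int(i) for i in range(z.shape[1]) if np.ptp(z[:, i]) == 0.0]
    return LatentFeatureMatrix(z, list(adjacency.node_order), flat)


def reconstruction_error(
    model: AutoencoderModel, adjacency: AdjacencyMatrix
) -> float:
    """Mean BCE between the adjacency and its reconstruction."""
    x = np.asarray(adjacency.entries, dtype=float)
    if x.shape[1] != model.n_input:
        raise ValueError(
            f"matrix width {x.shape[1]} does not match model input {model.n_input}"
        )
    return binary_cross_entropy(x, model.reconstruct(x))
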