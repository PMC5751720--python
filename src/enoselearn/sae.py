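"""Sparse auto-encoder: tied-weight encoding/decoding, the three-term cost,
exact gradients and mini-batch SGD training of a single layer.

A sparse auto-encoder maps an input x (m visible units, values in [0, 1])
through a sigmoid hidden layer y = S(W x + b) (n hidden units) and
reconstructs z = S(W^T y + b') with the *same* weight matrix (tied weights).
Its cost over a batch of B samples is

    J = (1/B) sum_i 1/2 ||x_i - z_i||^2              (reconstruction)
      + (lambda/2) sum_jk W_jk^2                     (weight decay)
      + beta sum_j KL(rho || rho_hat_j)              (sparsity)

where rho_hat_j is the mean activation of hidden unit j over the batch and
KL(p||q) = p log(p/q) + (1-p) log((1-p)/(1-q)).  The sparsity term drives
each unit's average activation toward a small target rho, so only a few
hidden units fire per input.  Gradients are exact (both encode- and
decode-path contributions to the tied W), validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["EncoderLayer", "SAEConfig", "TrainReport", "sigmoid", "encode",
           "decode", "mean_activation", "sae_cost", "sae_gradients",
           "sgd_step", "train_sae", "init_layer"]

# keeps KL logs finite; sigmoid outputs can round to 0/1 in float64
_RHO_CLIP = 1e-12


@dataclass
class EncoderLayer:
    """Tied-weight auto-encoder parameters.

    W has shape (n_hidden, m_visible); b is the encoder bias (n_hidden,);
    b_prime the decoder bias (m_visible,).  The decoder uses W.T — mutating
    W changes both directions.
    """

    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        n, m = self.W.shape
        if self.b.shape != (n,) or self.b_prime.shape != (m,):
            raise ValueError("bias shapes inconsistent with W")
        for a in (self.W, self.b, self.b_prime):
            if not np.all(np.isfinite(a)):
                raise ValueError("parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "EncoderLayer":
        return EncoderLayer(self.W.copy(), self.b.copy(), self.b_prime.copy())


@dataclass
class SAEConfig:
    """Hyper-parameters for one sparse auto-encoder layer.

    rho: sparsity target in (0, 1); beta: sparsity weight >= 0;
    lam: weight-decay coefficient >= 0; epsilon: SGD learning rate > 0.
    """

    n_hidden: int
    rho: float = 0.01
    beta: float = 0.1
    lam: float = 1e-4
    epsilon: float = 0.1
    epochs: int = 10
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.beta < 0 or self.lam < 0:
            raise ValueError("beta and lam must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.n_hidden < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("n_hidden/batch_size >= 1, epochs >= 0")


@dataclass
class TrainReport:
    """Per-epoch training diagnostics (one entry per epoch)."""

    cost: list[float] = field(default_factory=list)
    reconstruction: list[float] = field(default_factory=list)
    mean_hidden_activation: list[float] = field(default_factory=list)
    # set by fine-tuning, which logs both losses
    cross_entropy: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)


def sigmoid(u):
    """Numerically stable logistic function 1 / (1 + exp(-u))."""
    return expit(u)


def encode(layer: EncoderLayer, x: np.ndarray) -> np.ndarray:
    """Hidden activations y = S(W x + b).

    Accepts a single vector (m,) or a batch (B, m); returns matching shape.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.n_visible:
        raise ValueError(f"input dim {x.shape[-1]} != visible size {layer.n_visible}")
    return sigmoid(x @ layer.W.T + layer.b)


def decode(layer: EncoderLayer, y: np.ndarray) -> np.ndarray:
    """Reconstruction z = S(W^T y + b') with the tied weight matrix."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != layer.n_hidden:
        raise ValueError(f"hidden dim {y.shape[-1]} != hidden size {layer.n_hidden}")
    return sigmoid(y @ layer.W + layer.b_prime)


def mean_activation(layer: EncoderLayer, batch: np.ndarray) -> np.ndarray:
    """Per-hidden-unit mean activation rho_hat over a non-empty batch."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    return encode(layer, batch).mean(axis=0)


def _kl_term(rho: float, rho_hat: np.ndarray) -> float:
    q = np.clip(rho_hat, _RHO_CLIP, 1.0 - _RHO_CLIP)
    return float(np.sum(rho * np.log(rho / q)
                        + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - q))))


def sae_cost(layer: EncoderLayer, batch: np.ndarray, cfg: SAEConfig):
    """Total cost J and its three addends on a batch.

    Returns ``(J, reconstruction, weight_decay, sparsity)``.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    Y = encode(layer, X)
    Z = decode(layer, Y)
    recon = float(0.5 * np.sum((X - Z) ** 2) / X.shape[0])
    decay = float(0.5 * cfg.lam * np.sum(layer.W ** 2))
    sparsity = float(cfg.beta * _kl_term(cfg.rho, Y.mean(axis=0)))
    return recon + decay + sparsity, recon, decay, sparsity


def sae_gradients(layer: EncoderLayer, batch: np.ndarray, cfg: SAEConfig):
    """Exact gradients of :func:`sae_cost` w.r.t. W, b, b'.

    The tied W collects both paths: the encode-path delta times the input
    plus the hidden activation times the decode-path delta; the sparsity
    back-term beta (-rho/rho_hat + (1-rho)/(1-rho_hat)) / B enters at the
    hidden layer; weight decay adds lambda W.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    B = X.shape[0]
    Y = encode(layer, X)
    Z = decode(layer, Y)
    rho_hat = np.clip(Y.mean(axis=0), _RHO_CLIP, 1.0 - _RHO_CLIP)

    D2 = (Z - X) * Z * (1.0 - Z) / B                          # (B, m)
    kl_back = cfg.beta * (-cfg.rho / rho_hat
                          + (1.0 - cfg.rho) / (1.0 - rho_hat)) / B
    D1 = (D2 @ layer.W.T + kl_back) * Y * (1.0 - Y)           # (B, n)

    gW = D1.T @ X + Y.T @ D2 + cfg.lam * layer.W
    gb = D1.sum(axis=0)
    gb_prime = D2.sum(axis=0)
    return gW, gb, gb_prime


def sgd_step(layer: EncoderLayer, gradients, epsilon: float) -> EncoderLayer:
    """In-place gradient-descent update p <- p - epsilon * dJ/dp."""
    gW, gb, gb_prime = gradients
    layer.W -= epsilon * gW
    layer.b -= epsilon * gb
    layer.b_prime -= epsilon * gb_prime
    return layer


def init_layer(m_visible: int, n_hidden: int,
               rng: np.random.Generator) -> EncoderLayer:
    """Seeded sigmoid-suited initialization: W ~ U(+-4 sqrt(6/(m+n))), zero biases."""
    r = 4.0 * np.sqrt(6.0 / (m_visible + n_hidden))
    W = rng.uniform(-r, r, size=(n_hidden, m_visible))
    return EncoderLayer(W, np.zeros(n_hidden), np.zeros(m_visible))


def train_sae(data: np.ndarray, cfg: SAEConfig):
    """Train one sparse auto-encoder layer with mini-batch SGD.

    Per epoch: seeded shuffle, partition into mini-batches of
    ``cfg.batch_size``, one gradient step per mini-batch (rho_hat computed on
    that mini-batch).  The report logs the full-data cost and mean hidden
    activation after every epoch.  Data is expected in [0, 1]; values outside
    trigger a warning but training proceeds.

    Returns ``(EncoderLayer, TrainReport)``.
    """
    import warnings

    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.min() < 0.0 or X.max() > 1.0:
        warnings.warn("training data outside [0, 1]; sigmoid decoder cannot "
                      "reconstruct such values exactly", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    layer = init_layer(X.shape[1], cfg.n_hidden, rng)
    report = TrainReport()
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            mb = X[order[start:start + cfg.batch_size]]
            sgd_step(layer, sae_gradients(layer, mb, cfg), cfg.epsilon)
        J, recon, _, _ = sae_cost(layer, X, cfg)
        report.cost.append(J)
        report.reconstruction.append(recon)
        report.mean_hidden_activation.append(float(mean_activation(layer, X).mean()))
    return layer, report
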