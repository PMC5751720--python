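"""Stacked sparse auto-encoders and the softmax-headed classifier.

Greedy layer-wise pretraining trains each sparse auto-encoder on the hidden
representation of the previous one.  The trained encode halves are then
stacked, a softmax output layer is attached (one unit per class), the whole
network is initialized from the pretrained parameters, and supervised
fine-tuning updates every layer with mini-batch SGD.  The default
fine-tuning loss is softmax cross-entropy; a mean-squared-error variant
(one-hot targets vs. probabilities) is available via ``loss="mse"``, and the
MSE is always logged as a diagnostic regardless of which loss is optimized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sae import (EncoderLayer, SAEConfig, TrainReport, encode, train_sae,
                  sigmoid)

__all__ = ["ClassifierNet", "FineTuneConfig", "pretrain_stack",
           "build_classifier", "forward_classify", "fine_tune", "predict",
           "extract_deep_features", "save_net", "load_net"]


@dataclass
class ClassifierNet:
    """Stacked encoder layers plus a softmax head.

    ``layer_sizes`` runs input -> hidden sizes -> n_classes, e.g.
    [3640, 200, 100, 7].  Only the encode halves of the pretrained layers are
    kept (decoder biases are dropped after pretraining).
    """

    encoders: list[EncoderLayer]
    head_W: np.ndarray
    head_b: np.ndarray

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        for i, enc in enumerate(self.encoders):
            if enc.n_visible != sizes[i]:
                raise ValueError("encoder sizes do not chain")
        if self.head_W.shape[1] != self.encoders[-1].n_hidden:
            raise ValueError("head width inconsistent with last hidden layer")

    @property
    def layer_sizes(self) -> list[int]:
        return ([self.encoders[0].n_visible]
                + [e.n_hidden for e in self.encoders]
                + [self.head_W.shape[0]])

    @property
    def n_classes(self) -> int:
        return self.head_W.shape[0]


@dataclass
class FineTuneConfig:
    """Supervised fine-tuning hyper-parameters (epsilon2 = learning rate)."""

    epsilon2: float = 1.0
    epochs: int = 10
    batch_size: int = 10
    seed: int = 0
    loss: str = "xent"  # "xent" (softmax cross-entropy) or "mse"

    def __post_init__(self) -> None:
        if self.epsilon2 <= 0:
            raise ValueError("epsilon2 must be > 0")
        if self.loss not in ("xent", "mse"):
            raise ValueError("loss must be 'xent' or 'mse'")


def pretrain_stack(data: np.ndarray, layer_cfgs: list[SAEConfig]):
    """Greedy layer-wise unsupervised pretraining.

    Layer 1 trains on the raw vectors; layer i > 1 trains on the hidden
    activations of layer i-1.  Returns the trained layers in order.
    """
    if not layer_cfgs:
        raise ValueError("need at least one layer config")
    X = np.atleast_2d(np.asarray(data, dtype=float))
    layers: list[EncoderLayer] = []
    for cfg in layer_cfgs:
        layer, _ = train_sae(X, cfg)
        layers.append(layer)
        X = encode(layer, X)
    return layers


def build_classifier(stack: list[EncoderLayer], n_classes: int,
                     seed: int = 0) -> ClassifierNet:
    """Assemble the classifier: pretrained encoders + small-random softmax head.

    Encoder parameters are deep-copied, so later fine-tuning does not touch
    the pretrained stack.
    """
    if not stack:
        raise ValueError("stack must be non-empty")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    head_W = rng.uniform(-0.01, 0.01, size=(n_classes, stack[-1].n_hidden))
    head_b = np.zeros(n_classes)
    return ClassifierNet([layer.copy() for layer in stack], head_W, head_b)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_hidden(net: ClassifierNet, X: np.ndarray) -> list[np.ndarray]:
    """All layer activations [h0=X, h1, ..., hL] (sigmoid layers only)."""
    acts = [np.atleast_2d(np.asarray(X, dtype=float))]
    for enc in net.encoders:
        acts.append(sigmoid(acts[-1] @ enc.W.T + enc.b))
    return acts


def forward_classify(net: ClassifierNet, x: np.ndarray) -> np.ndarray:
    """Class probabilities: sigmoid encoders, then softmax over head logits."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if x.shape[-1] != net.layer_sizes[0]:
        raise ValueError(f"input dim {x.shape[-1]} != {net.layer_sizes[0]}")
    h = _forward_hidden(net, x)[-1]
    p = _softmax(h @ net.head_W.T + net.head_b)
    return p[0] if single else p


def _loss_and_logit_grad(P: np.ndarray, T: np.ndarray, loss: str):
    """Batch-mean loss value and dLoss/dlogits for the chosen loss."""
    B = P.shape[0]
    mse = float(np.mean(np.sum((P - T) ** 2, axis=1)))
    xent = float(-np.sum(T * np.log(np.clip(P, 1e-300, None))) / B)
    if loss == "xent":
        return xent, mse, (P - T) / B
    # MSE through the softmax Jacobian: dL/dlogit = p * (g - (g . p))
    g = 2.0 * (P - T) / B
    gl = P * (g - np.sum(g * P, axis=1, keepdims=True))
    return xent, mse, gl


def _backprop(net: ClassifierNet, X: np.ndarray, T: np.ndarray, loss: str):
    """Loss values and gradients for all parameters on one batch."""
    acts = _forward_hidden(net, X)
    hL = acts[-1]
    P = _softmax(hL @ net.head_W.T + net.head_b)
    xent, mse, d_logits = _loss_and_logit_grad(P, T, loss)

    g_head_W = d_logits.T @ hL
    g_head_b = d_logits.sum(axis=0)
    g_enc = []
    delta = (d_logits @ net.head_W) * hL * (1.0 - hL)
    for i in range(len(net.encoders) - 1, -1, -1):
        g_enc.append((delta.T @ acts[i], delta.sum(axis=0)))
        if i > 0:
            h = acts[i]
            delta = (delta @ net.encoders[i].W) * h * (1.0 - h)
    g_enc.reverse()
    return xent, mse, g_enc, g_head_W, g_head_b


def fine_tune(net: ClassifierNet, X: np.ndarray, labels: np.ndarray,
              cfg: FineTuneConfig):
    """Supervised mini-batch SGD on every layer (encoders + head).

    ``labels`` are integer class indices in [0, n_classes).  The report logs
    per-epoch full-data cross-entropy and the MSE between one-hot targets and
    probability vectors.  Returns ``(net, TrainReport)``; the net is updated
    in place.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= net.n_classes:
        raise ValueError("label outside [0, n_classes)")
    T = np.eye(net.n_classes)[labels]
    rng = np.random.default_rng(cfg.seed)
    report = TrainReport()
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, _, g_enc, g_hW, g_hb = _backprop(net, X[idx], T[idx], cfg.loss)
            for enc, (gW, gb) in zip(net.encoders, g_enc):
                enc.W -= cfg.epsilon2 * gW
                enc.b -= cfg.epsilon2 * gb
            net.head_W -= cfg.epsilon2 * g_hW
            net.head_b -= cfg.epsilon2 * g_hb
        xent, mse, _, _, _ = _backprop(net, X, T, cfg.loss)
        report.cross_entropy.append(xent)
        report.mse.append(mse)
    return net, report


def predict(net: ClassifierNet, X: np.ndarray) -> np.ndarray:
    """Argmax class indices; ties break to the lowest class index."""
    P = np.atleast_2d(forward_classify(net, X))
    return P.argmax(axis=1)


def extract_deep_features(stack_or_net, X: np.ndarray) -> np.ndarray:
    """Last-hidden-layer activations — the learned feature matrix.

    Accepts either a list of encoder layers or a ClassifierNet; in both
    cases the inputs pass through the sigmoid encode halves only.  These are
    the features fed to an SVM in the SSAE-SVM arm (deliberately *not*
    fine-tuned).
    """
    encoders = (stack_or_net.encoders if isinstance(stack_or_net, ClassifierNet)
                else stack_or_net)
    H = np.atleast_2d(np.asarray(X, dtype=float))
    for enc in encoders:
        H = encode(enc, H)
    return H


_FMT_VERSION = 1


def save_net(net: ClassifierNet, path, extra: dict | None = None) -> None:
    """Serialize a classifier (and optional scaler/config arrays) to NPZ."""
    payload = {"format_version": np.array(_FMT_VERSION),
               "n_layers": np.array(len(net.encoders)),
               "head_W": net.head_W, "head_b": net.head_b}
    for i, enc in enumerate(net.encoders):
        payload[f"W{i}"] = enc.W
        payload[f"b{i}"] = enc.b
        payload[f"b_prime{i}"] = enc.b_prime
    for k, v in (extra or {}).items():
        payload[f"extra_{k}"] = v
    np.savez(path, **payload)


def load_net(path):
    """Load a classifier saved by :func:`save_net`; returns (net, extra)."""
    data = np.load(path)
    if int(data["format_version"]) != _FMT_VERSION:
        raise ValueError("unsupported model container version")
    n_layers = int(data["n_layers"])
    encoders = [EncoderLayer(data[f"W{i}"], data[f"b{i}"], data[f"b_prime{i}"])
                for i in range(n_layers)]
    net = ClassifierNet(encoders, data["head_W"], data["head_b"])
    extra = {k[len("extra_"):]: data[k] for k in data.files if k.startswith("extra_")}
    return net, extra
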