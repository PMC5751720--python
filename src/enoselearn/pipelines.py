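"""End-to-end classification pipelines, one per comparison arm.

Every pipeline exposes ``fit(sample_set, train_idx)`` and
``predict(sample_set, idx)`` over a shared SampleSet, and fits *all* of its
learned state — unit scaler, z-scorer, reducer, auto-encoder pretraining,
fine-tuning — on the training indices only, so cross-validation is free of
information leakage by construction.

Arms
----
- ``SSAEPipeline``: flattened 1 Hz curves -> min-max unit scaling -> greedy
  sparse-auto-encoder pretraining -> softmax head -> fine-tuning (BPNN back
  end) or an SVM on the frozen deep features (SVM back end).  Setting
  ``beta=0`` gives the plain (non-sparse) stacked auto-encoder arm.
- ``TraditionalPipeline``: hand-crafted descriptors (method m1 or m2) ->
  z-score -> KECA or PCA -> BPNN or SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import SampleSet, flatten_sample, downsample, fit_unit_scaler
from .sae import SAEConfig
from .stack import (FineTuneConfig, pretrain_stack, build_classifier,
                    fine_tune, predict, extract_deep_features)
from . import baselines as bl

__all__ = ["SSAEPipeline", "TraditionalPipeline", "make_pipeline",
           "METHOD_NAMES"]


def _vectors_at_1hz(sample_set: SampleSet) -> np.ndarray:
    """Flattened per-sample input vectors, decimating to 1 Hz if needed."""
    rows = []
    for s in sample_set.samples:
        if s.sampling_rate_hz != 1.0:
            curves = [downsample(c, 1.0) for c in s.curves]
            rows.append(np.concatenate([c.values for c in curves]))
        else:
            rows.append(flatten_sample(s))
    return np.array(rows)


@dataclass
class SSAEPipeline:
    """Stacked (sparse) auto-encoder arm with a BPNN or SVM back end.

    ``hidden_sizes`` are the per-layer hidden widths; ``beta`` the sparsity
    weight shared across layers (0 disables sparsity -> plain SAE);
    pretraining/fine-tuning epoch budgets and learning rates follow the
    chosen configuration.
    """

    hidden_sizes: tuple = (200, 100)
    rho: float = 0.01
    beta: float = 0.1
    lam: float = 1e-4
    epsilon1: float = 0.1
    epsilon2: float = 1.0
    pretrain_epochs: int = 10
    finetune_epochs: int = 10
    batch_size: int = 10
    backend: str = "bpnn"        # "bpnn" (fine-tuned) or "svm" (frozen features)
    loss: str = "xent"
    seed: int = 0
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if self.backend not in ("bpnn", "svm"):
            raise ValueError("backend must be 'bpnn' or 'svm'")
        if not self.name:
            prefix = "SSAE" if self.beta > 0 else "SAE"
            self.name = f"{prefix}-{self.backend.upper()}"

    def fit(self, sample_set: SampleSet, train_idx) -> "SSAEPipeline":
        X = _vectors_at_1hz(sample_set)[np.asarray(train_idx)]
        y = sample_set.label_indices()[np.asarray(train_idx)]
        self._scaler = fit_unit_scaler(X)
        Xs = self._scaler.transform(X)
        cfgs = [SAEConfig(n_hidden=h, rho=self.rho, beta=self.beta,
                          lam=self.lam, epsilon=self.epsilon1,
                          epochs=self.pretrain_epochs,
                          batch_size=self.batch_size, seed=self.seed + i)
                for i, h in enumerate(self.hidden_sizes)]
        self._stack = pretrain_stack(Xs, cfgs)
        n_classes = len(sample_set.class_names)
        if self.backend == "bpnn":
            net = build_classifier(self._stack, n_classes, seed=self.seed + 101)
            ft = FineTuneConfig(epsilon2=self.epsilon2,
                                epochs=self.finetune_epochs,
                                batch_size=self.batch_size,
                                seed=self.seed + 202, loss=self.loss)
            self._net, self.report = fine_tune(net, Xs, y, ft)
        else:
            feats = extract_deep_features(self._stack, Xs)
            self._svm = bl.svm_train(feats, y)
        return self

    def predict(self, sample_set: SampleSet, idx) -> np.ndarray:
        X = _vectors_at_1hz(sample_set)[np.asarray(idx)]
        Xs = self._scaler.transform(X)
        if self.backend == "bpnn":
            return predict(self._net, Xs)
        feats = extract_deep_features(self._stack, Xs)
        return bl.svm_predict(self._svm, feats)


@dataclass
class TraditionalPipeline:
    """Hand-crafted feature arm: descriptors -> z-score -> reducer -> classifier.

    ``feature_method`` "m1" (wavelet + normalization, 10 descriptors/curve,
    KECA by default, 20 dims) or "m2" (Savitzky-Golay, 5 descriptors/curve,
    PCA by default, 19 dims).
    """

    feature_method: str = "m2"
    reducer: str = "pca"          # "pca" or "keca"
    n_components: int = 19
    classifier: str = "svm"       # "bpnn" or "svm"
    bpnn_hidden: tuple = (30,)
    bpnn_epochs: int = 200
    epsilon2: float = 1.0
    seed: int = 0
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.name:
            self.name = f"{self.reducer.upper()}-{self.classifier.upper()}"

    def _features(self, sample_set: SampleSet) -> np.ndarray:
        if not hasattr(self, "_feat_cache"):
            fm = bl.assemble_features(sample_set, self.feature_method)
            self._feat_cache = fm.values
        return self._feat_cache

    def fit(self, sample_set: SampleSet, train_idx) -> "TraditionalPipeline":
        train_idx = np.asarray(train_idx)
        F = self._features(sample_set)[train_idx]
        y = sample_set.label_indices()[train_idx]
        self._zscore = bl.fit_feature_scaler(F)
        Fz = bl.apply_feature_scaler(self._zscore, F)
        k = min(self.n_components, Fz.shape[0] - 1, Fz.shape[1])
        if self.reducer == "pca":
            self._red = bl.pca_fit(Fz, k)
            R = bl.pca_apply(self._red, Fz)
        else:
            self._red = bl.keca_fit(Fz, k)
            R = bl.keca_apply(self._red, Fz)
        if self.classifier == "svm":
            self._clf = bl.svm_train(R, y)
        else:
            ft = FineTuneConfig(epsilon2=self.epsilon2, epochs=self.bpnn_epochs,
                                batch_size=10, seed=self.seed)
            self._clf, self.report = bl.bpnn_on_features(
                R, y, self.bpnn_hidden, ft,
                n_classes=len(sample_set.class_names))
        return self

    def predict(self, sample_set: SampleSet, idx) -> np.ndarray:
        F = self._features(sample_set)[np.asarray(idx)]
        Fz = bl.apply_feature_scaler(self._zscore, F)
        R = (bl.pca_apply(self._red, Fz) if self.reducer == "pca"
             else bl.keca_apply(self._red, Fz))
        if self.classifier == "svm":
            return bl.svm_predict(self._clf, R)
        return predict(self._clf, R)


METHOD_NAMES = ("ssae-bpnn", "sae-bpnn", "ssae-svm", "keca-bpnn", "keca-svm",
                "pca-bpnn", "pca-svm")


def make_pipeline(method: str, seed: int = 0, **overrides):
    """Construct a named comparison arm ("ssae-bpnn", "pca-svm", ...)."""
    method = method.lower()
    if method == "ssae-bpnn":
        return SSAEPipeline(backend="bpnn", seed=seed, **overrides)
    if method == "sae-bpnn":
        return SSAEPipeline(backend="bpnn", beta=0.0, seed=seed, **overrides)
    if method == "ssae-svm":
        return SSAEPipeline(backend="svm", seed=seed, **overrides)
    if method in ("keca-bpnn", "keca-svm"):
        kw = dict(feature_method="m1", reducer="keca", n_components=20,
                  classifier=method.split("-")[1], seed=seed)
        kw.update(overrides)
        return TraditionalPipeline(**kw)
    if method in ("pca-bpnn", "pca-svm"):
        kw = dict(feature_method="m2", reducer="pca", n_components=19,
                  classifier=method.split("-")[1], seed=seed)
        kw.update(overrides)
        return TraditionalPipeline(**kw)
    raise ValueError(f"unknown method {method!r}; choose from {METHOD_NAMES}")
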