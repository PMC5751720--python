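"""Traditional e-nose processing arms used for comparison.

Method 1: wavelet denoising + conductivity normalization, ten hand-crafted
descriptors per curve (100 features for a 10-sensor panel), reduced with
kernel entropy component analysis (KECA).  Method 2: Savitzky-Golay
smoothing, five descriptors per curve (50 features), reduced with PCA.
Either feature set feeds a BPNN or an SVM.

KECA selects kernel eigenpairs by their contribution to a Renyi entropy
estimate, (sqrt(lambda_i) e_i^T 1)^2, rather than by eigenvalue — the pair
that looks small spectrally can carry most of the entropy.  Out-of-sample
points are projected with the Nystrom extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import savgol_filter
from scipy.spatial.distance import cdist, pdist
from scipy.stats import gmean, hmean
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .signal_io import ResponseCurve, SampleSet
from .sae import init_layer
from .stack import ClassifierNet, FineTuneConfig, fine_tune

__all__ = ["FeatureMatrix", "ReducerModel", "sg_filter", "wavelet_denoise",
           "conductivity_normalize", "features_m1", "features_m2",
           "assemble_features", "fit_feature_scaler", "apply_feature_scaler",
           "pca_fit", "pca_apply", "keca_fit", "keca_apply", "svm_train",
           "svm_predict", "bpnn_on_features"]

M1_FEATURE_NAMES = ["t_max", "rms", "mean", "gmean", "hmean", "max_deriv",
                    "t_max_deriv", "avg_diff", "integral_to_max",
                    "mean_curvature"]
M2_FEATURE_NAMES = ["max", "max_deriv", "value_at_max_deriv", "min_deriv",
                    "max_second_deriv"]


@dataclass
class FeatureMatrix:
    """Samples x features matrix with aligned names and labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name count != column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")


@dataclass
class ReducerModel:
    """Fitted dimensionality reducer (``kind`` in {"pca", "keca"})."""

    kind: str
    k: int
    # pca
    pca: PCA | None = None
    sign_flip: np.ndarray | None = None
    # keca
    X_train: np.ndarray | None = None
    sigma_k: float | None = None
    eigvecs: np.ndarray | None = None       # selected e_i, columns
    eigvals: np.ndarray | None = None       # selected lambda_i
    entropy_contrib: np.ndarray | None = field(default=None)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def sg_filter(curve: ResponseCurve, window: int = 51, order: int = 3) -> ResponseCurve:
    """Savitzky-Golay least-squares polynomial smoothing (length preserved)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if window > len(curve):
        raise ValueError("window longer than curve")
    smoothed = savgol_filter(curve.values, window, order, mode="interp")
    return ResponseCurve(curve.sensor_id, curve.sampling_rate_hz, smoothed)


def wavelet_denoise(curve: ResponseCurve, wavelet: str = "db4",
                    level: int = 4, threshold: float | None = None) -> ResponseCurve:
    """Wavelet shrinkage: soft-threshold detail coefficients, reconstruct.

    The default threshold is the universal rule sigma * sqrt(2 log n) with
    sigma estimated from the median absolute deviation of the finest detail
    band.  ``threshold=0`` reproduces the input (perfect reconstruction).
    """
    n = len(curve)
    if level < 1 or level > pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len):
        raise ValueError(f"level {level} infeasible for length {n}")
    coeffs = pywt.wavedec(curve.values, wavelet, level=level)
    if threshold is None:
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        threshold = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    if threshold > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, threshold, mode="soft")
                                for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet)[:n]
    return ResponseCurve(curve.sensor_id, curve.sampling_rate_hz, rec)


def conductivity_normalize(curve: ResponseCurve,
                           baseline_window_s: float = 5.0) -> ResponseCurve:
    """Divide by the pre-exposure baseline (mean of the first 5 s).

    Yields the relative response, which is invariant to a global gain on the
    raw conductivity.
    """
    n_base = max(1, int(round(baseline_window_s * curve.sampling_rate_hz)))
    baseline = float(curve.values[:n_base].mean())
    if baseline == 0.0:
        raise ValueError("zero baseline; cannot normalize")
    return ResponseCurve(curve.sensor_id, curve.sampling_rate_hz,
                         curve.values / baseline)


# ---------------------------------------------------------------------------
# Hand-crafted descriptors
# ---------------------------------------------------------------------------

def _derivatives(y: np.ndarray, dt: float):
    """First and second derivatives: central differences, one-sided at edges."""
    d1 = np.gradient(y, dt)
    d2 = np.gradient(d1, dt)
    return d1, d2


def _positive_shift(y: np.ndarray) -> np.ndarray:
    # geometric/harmonic means need strictly positive values
    if y.min() <= 0:
        return y - y.min() + 1e-9
    return y


def features_m1(curve: ResponseCurve) -> dict[str, float]:
    """Ten descriptors of one response curve (method-1 feature bank).

    In order: time of the response maximum (s, first occurrence), root mean
    square, arithmetic/geometric/harmonic means, maximum of the first
    derivative, its time (s), average differential (mean of first
    differences), trapezoid integral from t=0 to the maximum, and mean
    curvature |y''| / (1 + y'^2)^(3/2) averaged over interior points.
    """
    if len(curve) < 3:
        raise ValueError("curve too short for descriptors")
    y = curve.values
    dt = 1.0 / curve.sampling_rate_hz
    i_max = int(np.argmax(y))
    d1, d2 = _derivatives(y, dt)
    yp = _positive_shift(y)
    i_dmax = int(np.argmax(d1))
    curvature = np.abs(d2[1:-1]) / (1.0 + d1[1:-1] ** 2) ** 1.5
    vals = [
        i_max * dt,
        float(np.sqrt(np.mean(y ** 2))),
        float(np.mean(y)),
        float(gmean(yp)),
        float(hmean(yp)),
        float(d1[i_dmax]),
        i_dmax * dt,
        float(np.mean(np.diff(y))),
        float(np.trapezoid(y[: i_max + 1], dx=dt)),
        float(np.mean(curvature)),
    ]
    return dict(zip(M1_FEATURE_NAMES, vals))


def features_m2(curve: ResponseCurve) -> dict[str, float]:
    """Five descriptors: max value, max/min first derivative, the response
    at the first-derivative maximum, and max second derivative."""
    if len(curve) < 3:
        raise ValueError("curve too short for descriptors")
    y = curve.values
    d1, d2 = _derivatives(y, 1.0 / curve.sampling_rate_hz)
    i_dmax = int(np.argmax(d1))
    vals = [float(y.max()), float(d1[i_dmax]), float(y[i_dmax]),
            float(d1.min()), float(d2.max())]
    return dict(zip(M2_FEATURE_NAMES, vals))


def assemble_features(sample_set: SampleSet, method: str = "m1",
                      preprocess: bool = True, sg_window: int = 51,
                      sg_order: int = 3, wavelet: str = "db4",
                      wavelet_level: int = 4) -> FeatureMatrix:
    """Per-curve descriptors concatenated in panel order, raw (unstandardized).

    Method "m1" applies wavelet denoising + conductivity normalization then
    the ten-descriptor bank (10 sensors -> 100 columns); "m2" applies
    Savitzky-Golay smoothing then the five-descriptor bank (-> 50 columns).
    Z-scoring is a separate step (:func:`fit_feature_scaler`) so it can be
    fitted on training folds only.
    """
    if method not in ("m1", "m2"):
        raise ValueError("method must be 'm1' or 'm2'")
    names = None
    rows = []
    for sample in sample_set.samples:
        feats: dict[str, float] = {}
        for c in sample.curves:
            if method == "m1":
                if preprocess:
                    level = min(wavelet_level,
                                pywt.dwt_max_level(len(c), pywt.Wavelet(wavelet).dec_len))
                    c = wavelet_denoise(c, wavelet, max(1, level))
                    c = conductivity_normalize(c)
                f = features_m1(c)
            else:
                if preprocess and sg_window <= len(c):
                    c = sg_filter(c, sg_window, sg_order)
                f = features_m2(c)
            feats.update({f"{c.sensor_id}:{k}": v for k, v in f.items()})
        if names is None:
            names = list(feats)
        rows.append([feats[k] for k in names])
    return FeatureMatrix(np.array(rows), names or [], list(sample_set.labels))


def fit_feature_scaler(X: np.ndarray):
    """Column-wise z-score parameters (mean, sd) from a training matrix."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def apply_feature_scaler(scaler, X: np.ndarray) -> np.ndarray:
    mu, sd = scaler
    return (np.asarray(X, dtype=float) - mu) / sd


# ---------------------------------------------------------------------------
# Dimensionality reduction
# ---------------------------------------------------------------------------

def pca_fit(X: np.ndarray, k: int) -> ReducerModel:
    """PCA on the training matrix: top-k eigenvectors of the covariance.

    Components are ordered by descending eigenvalue; each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if k < 1 or k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(f"k={k} out of range for shape {X.shape}")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    comp = pca.components_
    flip = np.sign(comp[np.arange(k), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    pca.components_ = comp * flip[:, None]
    return ReducerModel(kind="pca", k=k, pca=pca, sign_flip=flip)


def pca_apply(model: ReducerModel, X: np.ndarray) -> np.ndarray:
    if model.kind != "pca":
        raise ValueError("not a PCA model")
    return model.pca.transform(np.asarray(X, dtype=float))


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median-heuristic kernel width for Gaussian kernels."""
    d = pdist(np.asarray(X, dtype=float))
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def keca_fit(X: np.ndarray, k: int, sigma_k: float | None = None) -> ReducerModel:
    """Kernel entropy component analysis on the training matrix.

    Builds the Gaussian kernel matrix K_ij = exp(-||xi-xj||^2 / (2 sigma^2)),
    eigendecomposes it, scores each eigenpair by its Renyi-entropy
    contribution (sqrt(lambda_i) e_i^T 1)^2, and keeps the k pairs with the
    largest contribution (not the largest eigenvalue).  Tiny negative
    eigenvalues from round-off are clamped to 0 and excluded.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    if sigma_k is None:
        sigma_k = median_pairwise_distance(X)
    if sigma_k <= 0:
        raise ValueError("sigma_k must be > 0")
    K = np.exp(-cdist(X, X, "sqeuclidean") / (2.0 * sigma_k ** 2))
    eigvals, eigvecs = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)
    contrib = eigvals * (eigvecs.sum(axis=0) ** 2)   # (sqrt(l) e^T 1)^2
    order = np.argsort(contrib)[::-1][:k]
    return ReducerModel(kind="keca", k=k, X_train=X, sigma_k=sigma_k,
                        eigvecs=eigvecs[:, order], eigvals=eigvals[order],
                        entropy_contrib=contrib[order])


def keca_apply(model: ReducerModel, X: np.ndarray) -> np.ndarray:
    """Project points onto the selected entropy components.

    Training points reproduce rows of [sqrt(lambda_i) e_i]; new points use
    the Nystrom extension K(x, X_train) E Lambda^{-1/2}.
    """
    if model.kind != "keca":
        raise ValueError("not a KECA model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Kx = np.exp(-cdist(X, model.X_train, "sqeuclidean")
                / (2.0 * model.sigma_k ** 2))
    inv_sqrt = np.where(model.eigvals > 0, 1.0 / np.sqrt(
        np.where(model.eigvals > 0, model.eigvals, 1.0)), 0.0)
    return Kx @ model.eigvecs * inv_sqrt


# ---------------------------------------------------------------------------
# Classifier backends
# ---------------------------------------------------------------------------

def svm_train(X: np.ndarray, labels, kernel: str = "rbf", C: float = 1.0,
              gamma="scale") -> SVC:
    """Multiclass SVM (one-vs-one, RBF kernel, C=1 by default)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 classes")
    clf = SVC(kernel=kernel, C=C, gamma=gamma,
              decision_function_shape="ovo", random_state=0)
    clf.fit(np.asarray(X, dtype=float), labels)
    return clf


def svm_predict(clf: SVC, X: np.ndarray) -> np.ndarray:
    return clf.predict(np.asarray(X, dtype=float))


def bpnn_on_features(X: np.ndarray, labels: np.ndarray, hidden_sizes,
                     cfg: FineTuneConfig, n_classes: int | None = None):
    """Back-propagation network on a feature matrix, randomly initialized.

    Reuses the stacked-network machinery but skips pretraining: hidden
    layers start from the seeded sigmoid-suited random initialization.
    Returns ``(ClassifierNet, TrainReport)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(cfg.seed)
    sizes = [X.shape[1]] + list(hidden_sizes)
    encoders = [init_layer(sizes[i], sizes[i + 1], rng)
                for i in range(len(sizes) - 1)]
    head_W = rng.uniform(-0.01, 0.01, size=(n_classes, sizes[-1]))
    net = ClassifierNet(encoders, head_W, np.zeros(n_classes))
    return fine_tune(net, X, labels, cfg)
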