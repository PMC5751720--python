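import numpy as np
import pytest

import enoselearn as el
from enoselearn.pipelines import _vectors_at_1hz


@pytest.fixture(scope="session")
def small_cfg():
    """A fast simulator configuration generated directly at 1 Hz."""
    return el.SynthConfig(n_classes=4, reps_per_class=25, n_sensors=3,
                          duration_s=60, rate_hz=1.0, t_inject=5, t_peak=20,
                          tau_rise=4, tau_decay=30, seed=3)


@pytest.fixture(scope="session")
def small_set(small_cfg):
    return el.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_vectors(small_set):
    """Flattened, unit-scaled input vectors for the small dataset."""
    X = _vectors_at_1hz(small_set)
    scaler = el.fit_unit_scaler(X)
    return scaler.transform(X), small_set.label_indices()


@pytest.fixture(scope="session")
def default_set_1hz():
    """The full default dataset (7 classes x 30 reps x 10 sensors, 364 s)
    generated at 1 Hz — the downstream classification fixture."""
    return el.generate_dataset(el.SynthConfig(rate_hz=1.0, seed=11))


def rel_err(a, b):
    return abs(a - b) / max(1e-8, abs(a) + abs(b))


def max_grad_rel_err(value_fn, params_and_grads, h=1e-5):
    """Largest symmetric relative error between analytic gradients and
    central finite differences, sweeping every parameter entry."""
    worst = 0.0
    for arr, grad in params_and_grads:
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + h
            jp = value_fn()
            arr[i] = old - h
            jm = value_fn()
            arr[i] = old
            fd = (jp - jm) / (2 * h)
            worst = max(worst, rel_err(fd, grad[i]))
    return worst
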