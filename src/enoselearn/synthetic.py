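"""Synthetic MOS gas-sensor array datasets.

Metal-oxide-semiconductor (MOS) sensors respond to a volatile pulse with a
fast conductivity rise after injection, a peak, and a slow exponential
recovery toward baseline.  The generator emulates a 10-sensor panel measuring
7 liquor classes, 30 replicates each (210 measurements), 364 s recordings at
100 Hz — with class identity encoded purely as a per-sensor peak-amplitude
fingerprint, the simplest structure under which a feature learner must pick
up amplitude patterns across the panel.

The deterministic response kernel for one sensor with peak amplitude ``a``:

    r(t) = baseline                                          t <  t_inject
    r(t) = baseline + a (1 - exp(-(t - t_inject)/tau_rise))  t_inject <= t < t_peak
    r(t) = baseline + r_peak exp(-(t - t_peak)/tau_decay)    t >= t_peak

with ``r_peak = a (1 - exp(-(t_peak - t_inject)/tau_rise))`` so the curve is
continuous at the peak.  On top: i.i.d. Gaussian noise and a per-curve linear
baseline drift with random slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_io import ResponseCurve, LiquorSample, SampleSet

__all__ = ["SynthConfig", "ClassProfile", "make_class_profiles",
           "simulate_curve", "generate_dataset"]

_CLASS_NAMES = ["BFH", "BNWJ", "HJJ", "LJJ", "LZLJ", "MZDQ", "NLS"]


@dataclass
class SynthConfig:
    """Acquisition geometry and noise model for the simulator.

    Defaults mirror the target acquisition: 7 classes x 30 replicates,
    10 sensors, 364 s at 100 Hz.  ``class_separation`` (delta) scales how far
    class amplitude fingerprints spread around the common amplitude scale;
    ``noise_sd`` is the additive Gaussian noise sd in instrument units.
    ``rate_hz`` may be set to 1.0 to generate directly at the analysis rate
    and skip the 100x decimation (useful for fast experimentation).
    """

    n_classes: int = 7
    reps_per_class: int = 30
    n_sensors: int = 10
    duration_s: float = 364.0
    rate_hz: float = 100.0
    t_inject: float = 20.0
    tau_rise: float = 15.0
    tau_decay: float = 120.0
    t_peak: float = 80.0
    baseline_level: float = 0.5
    class_separation: float = 0.6
    amplitude_scale: float = 2.0
    noise_sd: float = 0.02
    drift_slope_sd: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.duration_s, self.rate_hz, self.tau_rise, self.tau_decay,
               self.amplitude_scale) <= 0:
            raise ValueError("durations, rates, taus and amplitude_scale must be positive")
        if not (0 <= self.t_inject < self.t_peak < self.duration_s):
            raise ValueError("need 0 <= t_inject < t_peak < duration_s")
        if self.noise_sd < 0 or self.class_separation < 0 or self.drift_slope_sd < 0:
            raise ValueError("noise_sd, class_separation, drift_slope_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassProfile:
    """Per-sensor peak amplitudes for one class (its volatile fingerprint)."""

    class_id: str
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


def _class_names(n: int) -> list[str]:
    if n <= len(_CLASS_NAMES):
        return _CLASS_NAMES[:n]
    return _CLASS_NAMES + [f"C{i}" for i in range(len(_CLASS_NAMES), n)]


def make_class_profiles(cfg: SynthConfig) -> list[ClassProfile]:
    """Draw one amplitude fingerprint per class, deterministically from seed.

    Amplitude of class c on sensor k is
    ``amplitude_scale * (1 + delta * u_ck)`` with ``u_ck ~ U(-1, 1)`` i.i.d.
    With ``delta = 0`` every class shares one fingerprint and classes are
    indistinguishable in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    u = rng.uniform(-1.0, 1.0, size=(cfg.n_classes, cfg.n_sensors))
    names = _class_names(cfg.n_classes)
    amps = cfg.amplitude_scale * (1.0 + cfg.class_separation * u)
    return [ClassProfile(names[c], np.clip(amps[c], 0.0, None))
            for c in range(cfg.n_classes)]


def _kernel(t: np.ndarray, a: float, cfg: SynthConfig) -> np.ndarray:
    r = np.full_like(t, cfg.baseline_level)
    rising = (t >= cfg.t_inject) & (t < cfg.t_peak)
    r[rising] += a * (1.0 - np.exp(-(t[rising] - cfg.t_inject) / cfg.tau_rise))
    r_peak = a * (1.0 - np.exp(-(cfg.t_peak - cfg.t_inject) / cfg.tau_rise))
    decaying = t >= cfg.t_peak
    r[decaying] += r_peak * np.exp(-(t[decaying] - cfg.t_peak) / cfg.tau_decay)
    return r


def simulate_curve(amplitude: float, cfg: SynthConfig,
                   rng: np.random.Generator,
                   sensor_id: str = "S0") -> ResponseCurve:
    """Simulate one sensor curve: kernel + Gaussian noise + linear drift."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n = int(round(cfg.duration_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz
    values = _kernel(t, amplitude, cfg)
    if cfg.drift_slope_sd > 0:
        values = values + rng.normal(0.0, cfg.drift_slope_sd) * t
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=n)
    return ResponseCurve(sensor_id, cfg.rate_hz, values)


def generate_dataset(cfg: SynthConfig) -> SampleSet:
    """Generate the full labeled SampleSet (n_classes x reps_per_class).

    Fully determined by ``cfg.seed``: the class fingerprints come from the
    seed itself and the noise stream from a child generator, so two runs
    with the same config are identical.
    """
    profiles = make_class_profiles(cfg)
    rng = np.random.default_rng((cfg.seed, 1))
    panel = [f"S{k}" for k in range(cfg.n_sensors)]
    samples = []
    for profile in profiles:
        for _ in range(cfg.reps_per_class):
            curves = [simulate_curve(profile.amplitudes[k], cfg, rng, panel[k])
                      for k in range(cfg.n_sensors)]
            samples.append(LiquorSample(curves, profile.class_id))
    return SampleSet(samples, [p.class_id for p in profiles], panel)
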