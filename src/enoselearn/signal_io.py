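"""Reading, writing and shaping multi-sensor response recordings.

An electronic-nose measurement is a panel of gas sensors sampled
simultaneously over one exposure-and-recovery cycle.  This module holds the
containers for a single sensor curve, a labeled multi-sensor measurement and
a labeled collection of measurements, together with the plumbing every
downstream stage needs: a flat CSV dialect, integer decimation (e.g.
100 Hz -> 1 Hz), flattening a measurement into one long input vector, and a
min-max scaler onto the unit interval (a sigmoid decoder can only
reconstruct values in (0, 1), so network inputs must live there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseCurve",
    "LiquorSample",
    "SampleSet",
    "read_sample_set",
    "write_sample_set",
    "downsample",
    "flatten_sample",
    "UnitScaler",
    "fit_unit_scaler",
    "apply_scaler",
]


@dataclass
class ResponseCurve:
    """One sensor's sampled response over a measurement.

    Parameters
    ----------
    sensor_id : str
        Label identifying the sensor within the panel.
    sampling_rate_hz : float
        Sampling rate in Hz; strictly positive.
    values : numpy.ndarray
        Sensor responses (instrument units, e.g. conductivity), time
        origin t = 0.
    """

    sensor_id: str
    sampling_rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must all be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t = 0 at the first sample)."""
        return np.arange(self.values.size) / self.sampling_rate_hz

    def __len__(self) -> int:
        return self.values.size


@dataclass
class LiquorSample:
    """One labeled multi-sensor measurement (one curve per panel sensor)."""

    curves: list[ResponseCurve]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("a sample needs at least one curve")
        rates = {c.sampling_rate_hz for c in self.curves}
        lengths = {len(c) for c in self.curves}
        if len(rates) != 1 or len(lengths) != 1:
            raise ValueError("all curves must share sampling rate and length")
        ids = [c.sensor_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise ValueError("sensor_ids within a sample must be unique")

    @property
    def sensor_ids(self) -> list[str]:
        return [c.sensor_id for c in self.curves]

    @property
    def sampling_rate_hz(self) -> float:
        return self.curves[0].sampling_rate_hz


@dataclass
class SampleSet:
    """An ordered, labeled collection of measurements sharing one panel."""

    samples: list[LiquorSample]
    class_names: list[str]
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.panel and self.samples:
            self.panel = list(self.samples[0].sensor_ids)
        for i, s in enumerate(self.samples):
            if s.sensor_ids != self.panel:
                raise ValueError(
                    f"sample {i} sensor order {s.sensor_ids} != panel {self.panel}"
                )
            if s.label is not None and s.label not in self.class_names:
                raise ValueError(f"sample {i} label {s.label!r} not in class_names")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.samples]

    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into class_names."""
        return np.array([self.class_names.index(s.label) for s in self.samples])


# ---------------------------------------------------------------------------
# CSV dialect: one wide table, one row per (sample, sensor).
# Header comment line carries the sampling rate and the class vocabulary;
# the column header is sample_id,label,sensor_id,v0,...,v{T-1}.
# ---------------------------------------------------------------------------

_META_PREFIX = "#enoselearn"


def write_sample_set(sample_set: SampleSet, path) -> None:
    """Write a SampleSet to one wide CSV file.

    The first line is a metadata comment (``rate_hz``, class vocabulary,
    panel); re-reading with :func:`read_sample_set` reproduces the set up to
    text round-trip precision.
    """
    rate = sample_set.samples[0].sampling_rate_hz if sample_set.samples else 1.0
    n_vals = len(sample_set.samples[0].curves[0]) if sample_set.samples else 0
    meta = (
        f"{_META_PREFIX} rate_hz={rate!r}"
        f" classes={','.join(sample_set.class_names)}"
        f" panel={','.join(sample_set.panel)}\n"
    )
    rows = []
    for i, s in enumerate(sample_set.samples):
        for c in s.curves:
            rows.append(
                [f"s{i:04d}", "" if s.label is None else s.label, c.sensor_id]
                + list(c.values)
            )
    cols = ["sample_id", "label", "sensor_id"] + [f"v{j}" for j in range(n_vals)]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_sample_set(path) -> SampleSet:
    """Read a SampleSet written by :func:`write_sample_set`.

    Raises
    ------
    ValueError
        If a sample is missing a panel sensor (the error names the sensor)
        or curve lengths are ragged.
    """
    with open(path) as fh:
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith(_META_PREFIX):
            raise ValueError(f"{path}: missing {_META_PREFIX} metadata header")
        meta = dict(
            tok.split("=", 1) for tok in meta_line[len(_META_PREFIX):].split() if "=" in tok
        )
        rate = float(meta["rate_hz"])
        class_names = [c for c in meta.get("classes", "").split(",") if c]
        panel = [p for p in meta.get("panel", "").split(",") if p]
        df = pd.read_csv(fh, dtype={"sample_id": str, "label": str,
                                    "sensor_id": str},
                         float_precision="round_trip")

    samples: list[LiquorSample] = []
    if len(df):
        value_cols = [c for c in df.columns if c.startswith("v")]
        for sid, grp in df.groupby("sample_id", sort=False):
            by_sensor = {row.sensor_id: row for row in grp.itertuples()}
            curves = []
            for sensor in panel:
                if sensor not in by_sensor:
                    raise ValueError(
                        f"sample {sid!r} is missing sensor column(s) for {sensor!r}"
                    )
                row = grp[grp.sensor_id == sensor].iloc[0]
                vals = row[value_cols].to_numpy(dtype=float)
                curves.append(ResponseCurve(sensor, rate, vals))
            label = grp.iloc[0]["label"]
            label = None if pd.isna(label) or label == "" else str(label)
            samples.append(LiquorSample(curves, label))
    return SampleSet(samples, class_names, panel)


def downsample(curve: ResponseCurve, target_rate_hz: float) -> ResponseCurve:
    """Decimate a curve to ``target_rate_hz`` by keeping every k-th value.

    Pure point decimation at phase 0 (no averaging or interpolation); the
    decimation factor k = sampling_rate / target_rate must be an integer.
    A 364 s recording at 100 Hz decimated to 1 Hz keeps 364 values.
    """
    factor = curve.sampling_rate_hz / target_rate_hz
    k = round(factor)
    if k < 1 or abs(factor - k) > 1e-9:
        raise ValueError(
            f"target rate {target_rate_hz} Hz does not evenly divide "
            f"{curve.sampling_rate_hz} Hz"
        )
    return ResponseCurve(curve.sensor_id, target_rate_hz, curve.values[::k].copy())


def flatten_sample(sample: LiquorSample) -> np.ndarray:
    """Concatenate the panel's curves, in panel order, into one vector.

    Ten 364-point curves give the 3640-dimensional network input vector.
    """
    return np.concatenate([c.values for c in sample.curves])


@dataclass
class UnitScaler:
    """Per-coordinate affine min-max map onto [0, 1].

    Fitted on a training collection only; applied values are clipped to
    [0, 1] so held-out data cannot leave the unit interval.  Coordinates
    that are constant in training map to 0.5.
    """

    mins: np.ndarray
    ranges: np.ndarray  # 0 flags a constant coordinate

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, 0.5)
        nz = self.ranges != 0
        scaled = (x[..., nz] - self.mins[nz]) / self.ranges[nz]
        out[..., nz] = np.clip(scaled, 0.0, 1.0)
        return out


def fit_unit_scaler(vectors) -> UnitScaler:
    """Fit a :class:`UnitScaler` on a collection of equal-length vectors."""
    X = np.asarray(list(vectors), dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty collection")
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    return UnitScaler(mins=mins, ranges=ranges)


def apply_scaler(scaler: UnitScaler, x: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler to one vector or a matrix of row vectors."""
    return scaler.transform(x)
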