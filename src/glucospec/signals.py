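"""Synthetic glucose-sensor signal generation.

Real glucose-oxidase (GOD) strip recordings are not redistributable, so this
module provides a parametric stand-in with the statistical structure the
downstream pipeline needs: a class-dependent baseline level (hypoglycemic /
normal / hyperglycemic bands), a slow physiological drift, occasional
meal-like excursions, and additive heteroscedastic sensor noise whose
amplitude grows with the glucose level.  The noise amplitude is what makes
the *spectral* content class-informative once traces are turned into
spectrograms: brighter high-frequency floors for higher glucose.

Everything is a pure function of (parameters, seed): the same call always
reproduces the same samples bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "GlucoseTrace",
    "DatasetManifest",
    "GENERATOR_BANDS",
    "NOISE_SD",
    "DRIFT_MARGIN",
    "simulate_glucose_trace",
    "add_highfreq_noise",
    "simulate_dataset",
    "write_trace_csv",
    "read_trace_csv",
]


class ClassLabel(Enum):
    """Glucose regime label; numeric tags follow the -1/0/1 convention."""

    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"

    @property
    def numeric_tag(self) -> int:
        return {"low": -1, "normal": 0, "high": 1}[self.value]

    @classmethod
    def from_numeric(cls, tag: int) -> "ClassLabel":
        mapping = {-1: cls.LOW, 0: cls.NORMAL, 1: cls.HIGH}
        try:
            return mapping[int(tag)]
        except KeyError:
            raise ValueError(f"numeric_tag must be one of -1, 0, 1; got {tag}")

    @classmethod
    def coerce(cls, value) -> "ClassLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls(value.lower())
        return cls.from_numeric(value)


#: Baseline bands (mg/dL) the per-trace constant level is drawn from.
GENERATOR_BANDS: dict[ClassLabel, tuple[float, float]] = {
    ClassLabel.LOW: (45.0, 70.0),
    ClassLabel.NORMAL: (80.0, 140.0),
    ClassLabel.HIGH: (180.0, 320.0),
}

#: White sensor-noise standard deviation per class (mg/dL).  Electrochemical
#: strip noise grows with the analyte concentration, so higher regimes are
#: noisier; this is also what separates the classes spectrally.
NOISE_SD: dict[ClassLabel, float] = {
    ClassLabel.LOW: 0.5,
    ClassLabel.NORMAL: 3.0,
    ClassLabel.HIGH: 12.0,
}

#: Drift amplitude range (mg/dL) and period range (s) of the slow sinusoid.
DRIFT_AMPLITUDE = (1.0, 3.0)
DRIFT_PERIOD_S = (120.0, 600.0)

#: Meal-like Gaussian excursions: count 0-2, amplitude and width ranges.
#: Widths are compressed relative to real postprandial dynamics so the bump
#: is visible inside a 60 s trace.
MEAL_COUNT_MAX = 2
MEAL_AMPLITUDE = (5.0, 20.0)
MEAL_WIDTH_S = (2.0, 6.0)

#: Worst-case shift of the trace mean away from the sampled baseline due to
#: drift plus meal bumps (mg/dL); trace means stay within the class band
#: widened by this margin, which keeps the classes separable by mean alone.
DRIFT_MARGIN = 9.0

#: Physiological clamp (mg/dL).
CLAMP = (20.0, 500.0)


@dataclass
class GlucoseTrace:
    """A uniformly sampled glucose signal with label and provenance seed."""

    samples: np.ndarray
    fs_hz: float
    label: ClassLabel
    seed: int
    duration_s: float
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        n_expected = round(self.duration_s * self.fs_hz)
        if len(self.samples) != n_expected:
            raise ValueError(
                f"samples has length {len(self.samples)}, expected "
                f"round(duration_s * fs_hz) = {n_expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if np.any(self.samples <= 0):
            raise ValueError("samples must all be positive (mg/dL)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz


def simulate_glucose_trace(
    label, duration_s: float = 60.0, fs_hz: float = 100.0, seed: int = 0
) -> GlucoseTrace:
    """Simulate one glucose trace for the given regime.

    The signal is baseline + slow sinusoidal drift + 0-2 meal-like Gaussian
    bumps + white noise (class-dependent SD), clamped to [20, 500] mg/dL.
    Deterministic given (label, duration_s, fs_hz, seed).
    """
    label = ClassLabel.coerce(label)
    if duration_s is None or duration_s < 5:
        raise ValueError(f"duration_s must be >= 5 s, got {duration_s}")
    if fs_hz is None or fs_hz < 20:
        raise ValueError(f"fs_hz must be >= 20 Hz, got {fs_hz}")

    rng = np.random.default_rng(seed)
    n = round(duration_s * fs_hz)
    t = np.arange(n) / fs_hz

    lo, hi = GENERATOR_BANDS[label]
    baseline = rng.uniform(lo, hi)

    amp = rng.uniform(*DRIFT_AMPLITUDE)
    period = rng.uniform(*DRIFT_PERIOD_S)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    drift = amp * np.sin(2.0 * math.pi * t / period + phase)

    bumps = np.zeros(n)
    for _ in range(rng.integers(0, MEAL_COUNT_MAX + 1)):
        b_amp = rng.uniform(*MEAL_AMPLITUDE)
        b_center = rng.uniform(0.0, duration_s)
        b_width = rng.uniform(*MEAL_WIDTH_S)
        bumps += b_amp * np.exp(-0.5 * ((t - b_center) / b_width) ** 2)

    noise = rng.normal(0.0, NOISE_SD[label], size=n)

    samples = np.clip(baseline + drift + bumps + noise, *CLAMP)
    return GlucoseTrace(
        samples=samples,
        fs_hz=float(fs_hz),
        label=label,
        seed=int(seed),
        duration_s=float(duration_s),
        trace_id=f"{label.value}-{seed}",
    )


def add_highfreq_noise(trace: GlucoseTrace, snr_db: float, seed: int = 0) -> GlucoseTrace:
    """Corrupt a trace with white noise at an exact empirical SNR.

    ``snr_db = math.inf`` is the no-noise sentinel and returns an identical
    trace.  Otherwise the added noise is rescaled so that the realized
    signal-to-noise ratio (mean-square power ratio) matches the request
    exactly.  The label and metadata are preserved.
    """
    if len(trace.samples) == 0:
        raise ValueError("trace is empty")
    if snr_db is None or math.isnan(snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    if math.isinf(snr_db) and snr_db > 0:
        return GlucoseTrace(
            samples=trace.samples.copy(),
            fs_hz=trace.fs_hz,
            label=trace.label,
            seed=trace.seed,
            duration_s=trace.duration_s,
            trace_id=trace.trace_id,
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(trace.samples))
    p_signal = float(np.mean(trace.samples**2))
    p_target = p_signal / (10.0 ** (snr_db / 10.0))
    noise *= math.sqrt(p_target / float(np.mean(noise**2)))
    noisy = trace.samples + noise
    # Glucose is strictly positive; a pathologically low SNR could cross zero.
    noisy = np.maximum(noisy, 1e-3)
    return GlucoseTrace(
        samples=noisy,
        fs_hz=trace.fs_hz,
        label=trace.label,
        seed=int(seed),
        duration_s=trace.duration_s,
        trace_id=trace.trace_id,
    )


@dataclass
class DatasetManifest:
    """Stratified 80/20 train/test assignment for a simulated dataset."""

    entries: list = field(default_factory=list)  # dicts: index, trace_id, label, split
    seed: int = 0

    def indices(self, split: str) -> list[int]:
        return [e["index"] for e in self.entries if e["split"] == split]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "entries": [
                    {**e, "label": e["label"].value if isinstance(e["label"], ClassLabel) else e["label"]}
                    for e in self.entries
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        entries = [
            {**e, "label": ClassLabel(e["label"])} for e in obj["entries"]
        ]
        return cls(entries=entries, seed=obj.get("seed", 0))


def simulate_dataset(
    n_per_class: int,
    duration_s: float = 60.0,
    fs_hz: float = 100.0,
    seed: int = 0,
) -> tuple[list[GlucoseTrace], DatasetManifest]:
    """Simulate ``3 * n_per_class`` traces with a stratified 80/20 split.

    Per-trace seeds and the split assignment both derive deterministically
    from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    traces: list[GlucoseTrace] = []
    entries = []
    idx = 0
    for label in (ClassLabel.LOW, ClassLabel.NORMAL, ClassLabel.HIGH):
        trace_seeds = rng.integers(0, 2**31 - 1, size=n_per_class)
        n_test = int(round(0.2 * n_per_class))
        order = rng.permutation(n_per_class)
        split_of = {int(j): ("test" if rank < n_test else "train") for rank, j in enumerate(order)}
        for j in range(n_per_class):
            tr = simulate_glucose_trace(label, duration_s, fs_hz, int(trace_seeds[j]))
            tr.trace_id = f"{label.value}-{j:04d}"
            traces.append(tr)
            entries.append(
                {"index": idx, "trace_id": tr.trace_id, "label": label, "split": split_of[j]}
            )
            idx += 1
    return traces, DatasetManifest(entries=entries, seed=int(seed))


def write_trace_csv(trace: GlucoseTrace, path) -> None:
    """Write a trace as a two-column CSV ``t_seconds,glucose_mgdl``."""
    df = pd.DataFrame({"t_seconds": trace.times, "glucose_mgdl": trace.samples})
    df.to_csv(path, index=False)


def read_trace_csv(path, label=ClassLabel.NORMAL, seed: int = 0) -> GlucoseTrace:
    """Read a trace CSV (header ``t_seconds,glucose_mgdl`` required)."""
    df = pd.read_csv(path)
    for col in ("t_seconds", "glucose_mgdl"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing required column {col!r} in {path}")
    t = df["t_seconds"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"trace CSV {path} has fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    fs = 1.0 / dt
    return GlucoseTrace(
        samples=df["glucose_mgdl"].to_numpy(dtype=float),
        fs_hz=fs,
        label=ClassLabel.coerce(label),
        seed=seed,
        duration_s=len(t) / fs,
        trace_id=str(Path(path).stem),
    )
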