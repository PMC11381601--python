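"""Assembly of image datasets from simulated traces.

Bridges the signal generator and the classifier: simulate labeled traces,
cut them into 5 s segments, render one spectrogram image per segment, and
return train/test arrays split at the *trace* level (the stratified 80/20
manifest), so no trace leaks segments into both splits.
"""

from __future__ import annotations

import math

import numpy as np

from glucospec.enhancement import AWBKEnhancer
from glucospec.signals import ClassLabel, simulate_dataset, simulate_glucose_trace
from glucospec.spectrogram import trace_to_images

__all__ = ["images_from_traces", "make_classification_dataset", "make_imbalanced_dataset"]

#: Default rendering parameters of the scaled-down experiments.
DEFAULT_RENDER = dict(segment_s=5.0, window_s=1.0, hop_s=0.5, colormap="viridis", db_floor=-80.0)


def images_from_traces(traces, manifest, image_size=64, binary=False, **render_kwargs):
    """Render every trace's segments; split by the manifest assignment.

    Returns ``(X_train, y_train, X_test, y_test)`` with X uint8
    [N, H, W, 3] and y string labels.  ``binary=True`` collapses low + high
    into "abnormal" (vs "normal").
    """
    kwargs = {**DEFAULT_RENDER, **render_kwargs}
    out = {"train": ([], []), "test": ([], [])}
    for entry in manifest.entries:
        trace = traces[entry["index"]]
        label = trace.label.value
        if binary:
            label = "normal" if trace.label is ClassLabel.NORMAL else "abnormal"
        xs, ys = out[entry["split"]]
        for img in trace_to_images(trace, size=image_size, **kwargs):
            xs.append(img.pixels)
            ys.append(label)
    return _pack(out["train"]) + _pack(out["test"], image_size)


def _pack(split, image_size=None):
    xs, ys = split
    if not xs:
        return np.zeros((0, image_size or 0, image_size or 0, 3), dtype=np.uint8), np.array([], dtype=object)
    return np.stack(xs), np.array(ys, dtype=object)


def make_classification_dataset(
    n_segments_per_class: int = 200,
    duration_s: float = 60.0,
    fs_hz: float = 100.0,
    image_size: int = 64,
    seed: int = 0,
    binary: bool = False,
    enhance: bool = False,
    **render_kwargs,
):
    """The default synthetic fixture: ~``n_segments_per_class`` 5 s segments
    per class rendered at ``image_size``, trace-level 80/20 split."""
    kwargs = {**DEFAULT_RENDER, **render_kwargs}
    seg_per_trace = int(duration_s // kwargs["segment_s"])
    n_traces = math.ceil(n_segments_per_class / seg_per_trace)
    traces, manifest = simulate_dataset(n_traces, duration_s, fs_hz, seed)
    x_tr, y_tr, x_te, y_te = images_from_traces(
        traces, manifest, image_size=image_size, binary=binary, **kwargs
    )
    if enhance:
        enhancer = AWBKEnhancer()
        x_tr = enhancer.fit(x_tr).transform(x_tr)
        x_te = enhancer.transform(x_te)
    return x_tr, y_tr, x_te, y_te


def make_imbalanced_dataset(
    n_majority_traces: int = 16,
    imbalance_ratio: int = 4,
    duration_s: float = 60.0,
    fs_hz: float = 100.0,
    image_size: int = 64,
    seed: int = 0,
    **render_kwargs,
):
    """Majority-normal binary fixture (default 4:1 normal vs abnormal).

    The minority "abnormal" class mixes low and high traces evenly.  Split
    is stratified 80/20 at the trace level.  Returns the same 4-tuple as
    :func:`make_classification_dataset` with labels normal/abnormal.
    """
    if imbalance_ratio < 1:
        raise ValueError(f"imbalance_ratio must be >= 1, got {imbalance_ratio}")
    kwargs = {**DEFAULT_RENDER, **render_kwargs}
    rng = np.random.default_rng(seed)
    n_minority = max(2, n_majority_traces // imbalance_ratio)
    plan = [(ClassLabel.NORMAL, n_majority_traces)]
    plan += [(ClassLabel.LOW, n_minority - n_minority // 2), (ClassLabel.HIGH, n_minority // 2)]
    data = {"train": ([], []), "test": ([], [])}
    for label, count in plan:
        seeds = rng.integers(0, 2**31 - 1, size=count)
        n_test = max(1, int(round(0.2 * count)))
        order = rng.permutation(count)
        for rank, j in enumerate(order):
            split = "test" if rank < n_test else "train"
            trace = simulate_glucose_trace(label, duration_s, fs_hz, int(seeds[j]))
            name = "normal" if label is ClassLabel.NORMAL else "abnormal"
            xs, ys = data[split]
            for img in trace_to_images(trace, size=image_size, **kwargs):
                xs.append(img.pixels)
                ys.append(name)
    return _pack(data["train"], image_size) + _pack(data["test"], image_size)
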