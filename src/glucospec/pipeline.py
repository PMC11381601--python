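"""End-to-end pipeline orchestration with reproducible seed fan-out.

A single run goes simulate -> spectrograms -> enhancement -> training ->
evaluation -> explanation, writing every stage's artifacts into a run
directory together with a manifest listing each produced file with its
SHA-256 content hash.  A run is a pure function of (config, seed): the
global seed is fanned out into independent per-stage seeds through
``numpy.random.SeedSequence`` spawning (a splitmix-style derivation), so a
stage can be re-run on its own and still reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from glucospec.classifier import SpectrogramClassifier
from glucospec.datasets import images_from_traces
from glucospec.enhancement import AWBKEnhancer
from glucospec.evaluation import (
    classification_metrics,
    confusion_matrix,
    diagnostic_odds_ratio,
    roc_curve,
)
from glucospec.shapley import sampled_shapley, shap_overlay, superpixel_partition
from glucospec.signals import ClassLabel, simulate_dataset, write_trace_csv
from glucospec.spectrogram import SpectrogramImage

logger = logging.getLogger("glucospec.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]


def _strict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateSection:
    n_per_class: int = 5
    duration_s: float = 60.0
    fs_hz: float = 100.0


@dataclass
class SpectrogramSection:
    segment_s: float = 5.0
    window_s: float = 1.0
    hop_s: float = 0.5
    image_size: int = 64
    colormap: str = "viridis"
    db_floor: float = -80.0
    cutoff_hz: float | None = None
    denoise_levels: int = 3
    keep_detail_from: int = 3


@dataclass
class EnhanceSection:
    enabled: bool = True
    kernel: int = 5
    sigma_spatial: float = 2.0
    sigma_range: float = 30.0
    otsu_ratio: float = 2.0


@dataclass
class TrainSection:
    learning_rate: float = 1e-3
    kernel: int = 4
    n_filters: int = 32
    stride: int = 2
    n_epochs: int = 10
    dropout: float = 0.3
    batch_size: int = 32
    fc_nodes: int = 40
    lstm_hidden: int = 32
    n_conv_blocks: int = 2
    use_attention: bool = True
    loss: str = "modified"
    loss_t: float = 0.75
    loss_eta: float = 2.0


@dataclass
class ExplainSection:
    grid: int = 3
    n_samples: int = 100


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "runs/run0"
    n_classes: int = 3
    simulate: SimulateSection = field(default_factory=SimulateSection)
    spectrogram: SpectrogramSection = field(default_factory=SpectrogramSection)
    enhance: EnhanceSection = field(default_factory=EnhanceSection)
    train: TrainSection = field(default_factory=TrainSection)
    explain: ExplainSection = field(default_factory=ExplainSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "simulate": SimulateSection,
            "spectrogram": SpectrogramSection,
            "enhance": EnhanceSection,
            "train": TrainSection,
            "explain": ExplainSection,
        }
        kwargs = {}
        for key, section_cls in sections.items():
            if key in data:
                kwargs[key] = _strict(section_cls, data.pop(key) or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown keys in pipeline config: {sorted(unknown)}")
        return cls(**{**data, **kwargs})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def stage_seeds(seed: int, n: int = 6) -> list[int]:
    """Fan a global seed out into independent per-stage seeds (< 2^31)."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory.

    Stage order: simulate, spectrogram, enhance, train, evaluate, explain.
    Any stage failure raises with the stage named; artifacts written so far
    stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    artifacts: list[Path] = []
    timings = {}
    stage = "setup"
    try:
        # -- simulate --------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        sim = config.simulate
        traces, manifest = simulate_dataset(sim.n_per_class, sim.duration_s, sim.fs_hz, seeds[0])
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for trace in traces:
            path = trace_dir / f"{trace.trace_id}.csv"
            write_trace_csv(trace, path)
            artifacts.append(path)
        mpath = trace_dir / "manifest.json"
        mpath.write_text(manifest.to_json())
        artifacts.append(mpath)
        timings[stage] = time.perf_counter() - t0
        logger.info("simulate: %d traces in %.2fs", len(traces), timings[stage])

        # -- spectrogram -----------------------------------------------
        stage = "spectrogram"
        t0 = time.perf_counter()
        spec = config.spectrogram
        binary = config.n_classes == 2
        x_tr, y_tr, x_te, y_te = images_from_traces(
            traces,
            manifest,
            image_size=spec.image_size,
            binary=binary,
            segment_s=spec.segment_s,
            window_s=spec.window_s,
            hop_s=spec.hop_s,
            colormap=spec.colormap,
            db_floor=spec.db_floor,
            cutoff_hz=spec.cutoff_hz,
            denoise_levels=spec.denoise_levels,
            keep_detail_from=spec.keep_detail_from,
        )
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for i, (px, label) in enumerate(zip(x_te, y_te)):
            # binary mode collapses low+high to "abnormal", which has no
            # ClassLabel; sidecars then record the nearest canonical label
            canonical = ClassLabel(label) if label in ("low", "normal", "high") else ClassLabel.HIGH
            img = SpectrogramImage(
                pixels=px,
                label=canonical,
                colormap=spec.colormap,
                db_floor=spec.db_floor,
                source=f"test#{i}",
            )
            path = img_dir / f"test_{i:04d}.png"
            img.save_png(path)
            artifacts += [path, Path(str(path) + ".json")]
            if i >= 15:
                break  # a sample of rendered test images is enough on disk
        timings[stage] = time.perf_counter() - t0
        logger.info("spectrogram: %d train / %d test images in %.2fs", len(x_tr), len(x_te), timings[stage])

        # -- enhance ---------------------------------------------------
        stage = "enhance"
        t0 = time.perf_counter()
        if config.enhance.enabled:
            enh = config.enhance
            enhancer = AWBKEnhancer(enh.kernel, enh.sigma_spatial, enh.sigma_range, enh.otsu_ratio)
            x_tr = enhancer.fit(x_tr).transform(x_tr)
            x_te = enhancer.transform(x_te)
        timings[stage] = time.perf_counter() - t0

        # -- train -----------------------------------------------------
        stage = "train"
        t0 = time.perf_counter()
        tr = config.train
        clf = SpectrogramClassifier(
            learning_rate=tr.learning_rate,
            kernel=tr.kernel,
            n_filters=tr.n_filters,
            stride=tr.stride,
            n_epochs=tr.n_epochs,
            dropout=tr.dropout,
            batch_size=tr.batch_size,
            fc_nodes=tr.fc_nodes,
            lstm_hidden=tr.lstm_hidden,
            n_conv_blocks=tr.n_conv_blocks,
            image_size=config.spectrogram.image_size,
            n_classes=config.n_classes,
            use_attention=tr.use_attention,
            loss=tr.loss,
            loss_t=tr.loss_t,
            loss_eta=tr.loss_eta,
            seed=seeds[3],
        )
        clf.fit(x_tr, y_tr)
        ckpt = out / "checkpoint"
        clf.save_checkpoint(ckpt)
        artifacts += [ckpt / "config.json", ckpt / "parameters.npz", ckpt / "history.csv"]
        timings[stage] = time.perf_counter() - t0
        logger.info("train: %d epochs in %.2fs", tr.n_epochs, timings[stage])

        # -- evaluate --------------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        y_pred = clf.predict(x_te)
        classes = list(clf.classes_)
        cm = confusion_matrix(y_te, y_pred, classes)
        report = classification_metrics(cm)
        probs = clf.predict_proba(x_te)
        metrics = {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "f1": report.f1,
            "classes": classes,
        }
        if "normal" in classes and len(set(y_te)) >= 2:
            abnormal_true = np.asarray([v != "normal" for v in y_te])
            p_abnormal = 1.0 - probs[:, classes.index("normal")]
            points, auc = roc_curve(p_abnormal, abnormal_true, positive=True)
            abnormal_pred = np.asarray([v != "normal" for v in y_pred])
            cm2 = confusion_matrix(
                np.where(abnormal_true, "abnormal", "normal"),
                np.where(abnormal_pred, "abnormal", "normal"),
                ["abnormal", "normal"],
            )
            dor, corrected = diagnostic_odds_ratio(cm2)
            metrics.update({"auc_abnormal": auc, "dor": dor, "dor_corrected": corrected})
            roc_path = out / "roc.csv"
            with open(roc_path, "w") as fh:
                fh.write("fpr,tpr\n")
                for f_, t_ in points:
                    fh.write(f"{f_},{t_}\n")
            artifacts.append(roc_path)
        cm_path = out / "confusion_matrix.csv"
        cm.to_frame().to_csv(cm_path)
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        artifacts += [cm_path, metrics_path]
        timings[stage] = time.perf_counter() - t0
        logger.info("evaluate: accuracy %.3f in %.2fs", report.accuracy, timings[stage])

        # -- explain ---------------------------------------------------
        stage = "explain"
        t0 = time.perf_counter()
        ex = config.explain
        instance = x_te[0]
        background = x_tr.astype(np.float64).mean(axis=0).round().astype(np.uint8)
        partition = superpixel_partition(instance, ex.grid)
        target = int(clf.predict_proba(instance[None]).argmax())

        def predict_fn(images):
            return clf.predict_proba(images)[:, target]

        expl = sampled_shapley(
            predict_fn, instance, background, partition,
            n_samples=max(ex.n_samples, 10 * ex.grid**2), seed=seeds[5],
        )
        expl_path = out / "explanation.json"
        expl_path.write_text(expl.to_json())
        overlay = shap_overlay(instance, expl)
        overlay_path = out / "explanation_overlay.png"
        from PIL import Image

        Image.fromarray(overlay).save(overlay_path)
        artifacts += [expl_path, overlay_path]
        timings[stage] = time.perf_counter() - t0

        # -- manifest --------------------------------------------------
        stage = "manifest"
        run_manifest = {
            "config": config.to_dict(),
            "stage_seeds": seeds,
            "timings_s": timings,
            "files": [
                {"path": str(p.relative_to(out)), "sha256": _hash_file(p)}
                for p in artifacts
                if p.exists()
            ],
        }
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
        return out
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
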