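"""Training, evaluation and latency measurement.

Defaults mirror the reference recipe: Adam, batch size 8, learning rate
0.001, 100 epochs, joint optimisation of the three-head mean BCE; no early
stopping, LR schedule or augmentation; final-epoch checkpoint. Everything is
seeded (weight init, data order), so train -> evaluate reproduces identical
reports across runs on one machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import CariesDataset, DatasetSplit, split_dataset
from .errors import ConfigurationError
from .losses import total_loss
from .metrics import MetricsReport, evaluate_testset
from .model import DCDNet, DCDNetConfig
from .nn import Adam, no_grad

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "benchmark_fps",
           "save_checkpoint", "load_checkpoint", "overfit_fixtures"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 0.001
    epochs: int = 100
    optimizer: str = "adam"
    seed: int = 0
    dataset_dir: str | Path | None = None
    model: DCDNetConfig = field(default_factory=DCDNetConfig)
    max_steps: int | None = None  # optional cap for desk-scale experiments

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    model: DCDNet
    history: list[dict]
    steps: int
    checkpoint_path: Path | None = None


class InMemoryDataset:
    """A list of (image, mask) pairs with the batching interface of CariesDataset."""

    def __init__(self, pairs, label_counts=None):
        self.pairs = list(pairs)
        self.label_counts = label_counts

    def __len__(self):
        return len(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def batches(self, batch_size, rng=None):
        order = np.arange(len(self.pairs))
        if rng is not None:
            order = rng.permutation(order)
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            yield (np.stack([self.pairs[i][0] for i in idx]),
                   np.stack([self.pairs[i][1] for i in idx]))


def _train_split_dataset(config: TrainConfig):
    root = Path(config.dataset_dir)
    full = CariesDataset(root, input_hw=(config.model.input_h, config.model.input_w))
    split_path = root / "split.json"
    if split_path.exists():
        split = DatasetSplit.from_json(split_path)
    else:
        split = split_dataset(full.ids, 0.75, config.seed)
    return full.subset(split.train_ids), full.subset(split.test_ids), split


def train(config: TrainConfig, dataset=None, log_path=None,
          checkpoint_path=None, stop_fn=None) -> TrainResult:
    """Minimise the joint three-head BCE over the train split.

    dataset: optional in-memory dataset overriding config.dataset_dir (then
    no split is applied — every sample trains). stop_fn, if given, is called
    as stop_fn(model, step) after each optimiser step and may end training
    early (used by the seeded memorisation experiment).
    Writes a line-delimited JSON log and a final checkpoint when paths are
    given.
    """
    if dataset is None:
        if config.dataset_dir is None:
            raise ConfigurationError("either dataset or config.dataset_dir required")
        dataset, _, _ = _train_split_dataset(config)
    if len(dataset) == 0:
        raise ConfigurationError("empty train split")
    model = DCDNet(config.model)
    model.train()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    order_rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    log_fh = open(log_path, "w") if log_path else None
    step = 0
    try:
        for epoch in range(config.epochs):
            epoch_losses = []
            for images, masks in dataset.batches(config.batch_size, order_rng):
                model.zero_grad()
                outs = model.forward(images)
                loss, report = total_loss(masks, outs)
                loss.backward()
                opt.step()
                step += 1
                rec = {"epoch": epoch, "step": step, "loss": report.total,
                       "per_type": list(report.per_type)}
                epoch_losses.append(report.total)
                history.append(rec)
                if log_fh:
                    log_fh.write(json.dumps(rec) + "\n")
                if config.max_steps and step >= config.max_steps:
                    break
                if stop_fn is not None and stop_fn(model, step):
                    break
            else:
                continue
            break
    finally:
        if log_fh:
            log_fh.close()
    result = TrainResult(model=model, history=history, steps=step)
    if checkpoint_path:
        result.checkpoint_path = save_checkpoint(model, checkpoint_path)
    return result


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: DCDNet, path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(
        json.dumps(model.config.to_dict(), indent=2))
    return path


def load_checkpoint(path) -> DCDNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigurationError(f"missing config sidecar {sidecar}")
    config = DCDNetConfig.from_dict(json.loads(sidecar.read_text()))
    model = DCDNet(config)
    with np.load(path) as npz:
        try:
            model.load_state_dict({k: npz[k] for k in npz.files})
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"checkpoint {path} inconsistent with its config sidecar: {exc}"
            ) from exc
    return model


# ---------------------------------------------------------------------------
# evaluation and latency
# ---------------------------------------------------------------------------

def _predict_fn(model: DCDNet):
    def fn(batch):
        preds = model.predict(batch)
        return np.stack([p.maps for p in preds])
    return fn


def evaluate(model_or_checkpoint, dataset, threshold: float = 0.5,
             out_dir=None, model_name: str = "DCDNet",
             aggregate: str = "micro", overlays: bool = False) -> MetricsReport:
    """Per-type metrics over a dataset; optional CSV/JSON report + overlays.

    dataset: a CariesDataset / InMemoryDataset (or any (image, mask)
    sequence). Evaluation resolution is the model's output resolution and is
    recorded in the report.
    """
    model = (load_checkpoint(model_or_checkpoint)
             if not isinstance(model_or_checkpoint, DCDNet) else model_or_checkpoint)
    report = evaluate_testset(_predict_fn(model), dataset, threshold, aggregate)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rounded = report.round(2)
        rounded.to_json(out / "metrics.json")
        rounded.to_csv(out / "metrics.csv", model_name=model_name)
        if overlays:
            _write_overlays(model, dataset, out / "overlays", threshold)
    return report


def _write_overlays(model, dataset, out_dir, threshold):
    """Qualitative panels: prediction masks tinted R/G/B over the input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tints = np.eye(3) * 255
    for i, (image, _mask) in enumerate(dataset):
        pred = np.stack([p.maps for p in model.predict(image[None])])[0]
        base = np.repeat((np.clip(image, 0, 1) * 255)[..., None], 3, axis=2)
        for k in range(3):
            hit = pred[k] >= threshold
            base[hit] = 0.5 * base[hit] + 0.5 * tints[k]
        name = getattr(dataset, "ids", None)
        stem = name[i] if name else f"sample_{i:03d}"
        Image.fromarray(base.astype(np.uint8)).save(out_dir / f"{stem}_overlay.png")


def benchmark_fps(model: DCDNet, n_images: int = 10, warmup: int = 3) -> float:
    """Mean wall-clock milliseconds per single-image forward pass.

    Hardware-dependent; excluded from any correctness criterion. Warm-up
    passes are not counted.
    """
    if n_images < 10:
        raise ValueError("n_images must be >= 10 for a stable mean")
    cfg = model.config
    rng = np.random.default_rng(0)
    batch = rng.random((1, cfg.input_h, cfg.input_w), dtype=np.float32)
    model.eval()
    with no_grad():
        for _ in range(warmup):
            model.forward(batch)
        t0 = time.perf_counter()
        for _ in range(n_images):
            model.forward(batch)
        dt = time.perf_counter() - t0
    return dt / n_images * 1000.0


# ---------------------------------------------------------------------------
# the seeded memorisation (overfit) experiment
# ---------------------------------------------------------------------------

def overfit_fixtures(seed: int = 0, n_images: int = 8, input_hw=(32, 64),
                     backbone: str = "mobilenetv2", max_steps: int = 200,
                     check_every: int = 20, target_f1: float = 80.0,
                     threshold: float = 0.5):
    """Train on a tiny fixture set until it is memorised.

    Renders `n_images` synthetic cases directly at `input_hw` (geometry is
    canvas-proportional; a CPU-scale stand-in for full-resolution training),
    then runs Adam/batch-8/lr-0.001 for at most `max_steps` steps, checking
    training-set F1 every `check_every` steps and stopping once Types I and
    II both reach `target_f1`. Returns (MetricsReport, steps_used, history).
    """
    from .synthetic import FixtureSpec, generate_synthetic_case
    from .data import rasterize_annotations

    h, w = input_hw
    spec = FixtureSpec(n_images=n_images, height=h, width=w,
                       lesion_size_px=(max(6, h // 8), max(10, h // 4)),
                       noise_sd=4.0, seed=seed)
    pairs = []
    counts = np.zeros(3, dtype=int)
    for i in range(n_images):
        img, ann = generate_synthetic_case(spec, i)
        mask = rasterize_annotations(ann, h, w)
        pairs.append((img.pixels / 255.0, mask))
        counts += ann.counts()
    dataset = InMemoryDataset(pairs, label_counts=tuple(int(c) for c in counts))

    model_cfg = DCDNetConfig(backbone=backbone, input_h=h, input_w=w, seed=seed)
    cfg = TrainConfig(batch_size=8, learning_rate=0.001,
                      epochs=max(1, -(-max_steps // max(1, n_images // 8))),
                      seed=seed, model=model_cfg, max_steps=max_steps)

    state = {"report": None, "steps": 0}

    def stop_fn(model, step):
        if step % check_every:
            return False
        report = evaluate_testset(_predict_fn(model), dataset, threshold)
        state["report"], state["steps"] = report, step
        f1 = [report.per_type[t]["f1"] for t in ("Type I", "Type II")]
        return min(f1) >= target_f1

    result = train(cfg, dataset=dataset, stop_fn=stop_fn)
    if state["report"] is None or state["steps"] != result.steps:
        state["report"] = evaluate_testset(_predict_fn(result.model), dataset, threshold)
    return state["report"], result.steps, result.history
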