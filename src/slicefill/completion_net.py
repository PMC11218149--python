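"""Training regimes for the learned completion backend.

Two regimes mirror the two segmentation strategies under study:

* **leave-one-patient-out full supervision** — the network trains on every
  2D section of every cohort patient except the held-out one, then
  segments that patient from scratch (the fully automatic baseline);
* **per-volume sparse-annotation training** — the network trains *only*
  on the manually segmented sections of a single volume and is then asked
  to complete that same volume's withheld sections.  Overfitting the one
  patient is the point: the network memorises this anatomy and interpolates
  it across the gap.

Data hygiene is enforced and instrumented: withheld sections never enter a
batch, and every trained model records the exact slice indices and a
fingerprint of the arrays it saw.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._errors import ScheduleError, ShapeMismatchError
from .schedule import SparseLabelMap
from .unet import Adam, UNet2D, segmentation_loss
from .volume_io import LabelMap, Volume


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the encoder/decoder network."""

    depth: int = 3
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 3
    normalization: bool = True


#: larger preset comparable to a conventional full-scale U-Net
FULL_SCALE_SPEC = NetworkSpec(depth=4, base_channels=64)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    The historical regime is 200 epochs at batch size 16; the defaults
    keep those two values and add the choices the regime leaves open
    (Adam at 1e-3, cross-entropy + soft-Dice loss, per-volume z-score
    input normalisation).
    """

    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "ce+dice"
    seed: int = 0
    device: str = "cpu"
    normalization: str = "zscore"  # intensity normalisation: zscore | none
    early_stop: bool = False
    early_stop_patience: int = 20

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce it."""

    net: UNet2D
    spec: NetworkSpec
    config: TrainConfig
    data_fingerprint: str
    trained_slice_keys: list[tuple[int, int]]  # (patient, slice) pairs seen
    log: list[tuple[int, float]] = field(default_factory=list)  # (epoch, loss)

    def predict_volume(self, volume: Volume) -> LabelMap:
        """Segment every slice of a volume."""
        x = _normalize(volume.data, self.config.normalization)
        labels = np.empty(volume.shape, dtype=np.int16)
        for start in range(0, volume.n_slices, self.config.batch_size):
            batch = x[start:start + self.config.batch_size][:, None]
            labels[start:start + batch.shape[0]] = self.net.predict(batch)
        return LabelMap(labels, volume.spacing)

    def save(self, path) -> None:
        """Self-describing checkpoint: spec + config + log + weights."""
        meta = json.dumps({
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "data_fingerprint": self.data_fingerprint,
            "trained_slice_keys": [list(k) for k in self.trained_slice_keys],
            "log": self.log,
        })
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez_compressed(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        spec = NetworkSpec(**meta["spec"])
        config = TrainConfig(**meta["config"])
        net = build_network(spec, seed=config.seed)
        net.set_weights(weights)
        return cls(net=net, spec=spec, config=config,
                   data_fingerprint=meta["data_fingerprint"],
                   trained_slice_keys=[tuple(k) for k in meta["trained_slice_keys"]],
                   log=[tuple(e) for e in meta["log"]])


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet2D:
    """Instantiate the network from its spec (deterministic under seed)."""
    return UNet2D(depth=spec.depth, base_channels=spec.base_channels,
                  in_channels=spec.in_channels, n_classes=spec.out_channels,
                  normalization=spec.normalization, seed=seed)


def _normalize(data: np.ndarray, mode: str) -> np.ndarray:
    data = np.asarray(data, dtype=np.float32)
    if mode == "none":
        return data
    if mode == "zscore":
        std = data.std()
        return (data - data.mean()) / (std if std > 0 else 1.0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def _fingerprint(images: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(images).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()


def _train(images: np.ndarray, labels: np.ndarray, slice_keys, spec: NetworkSpec,
           cfg: TrainConfig, batch_hook=None) -> TrainedModel:
    """Core loop shared by both regimes.

    ``images`` is (n, H, W) already normalised, ``labels`` (n, H, W) int.
    ``batch_hook(epoch, keys)`` is called with the slice keys of every
    batch (used by tests to audit data hygiene).
    """
    net = build_network(spec, seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = images.shape[0]
    log: list[tuple[int, float]] = []
    best = np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            if batch_hook is not None:
                batch_hook(epoch, [slice_keys[i] for i in sel])
            x = images[sel][:, None]
            y = labels[sel]
            scores = net.forward(x)
            loss, dscores = segmentation_loss(scores, y, cfg.loss)
            net.backward(dscores)
            opt.step(net.gradients())
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        log.append((epoch, mean_loss))
        if cfg.early_stop:
            if mean_loss < best - 1e-5:
                best, stall = mean_loss, 0
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break
    return TrainedModel(net=net, spec=spec, config=cfg,
                        data_fingerprint=_fingerprint(images, labels),
                        trained_slice_keys=list(slice_keys), log=log)


def train_full_supervision(cohort, exclude_patient: int, spec: NetworkSpec,
                           cfg: TrainConfig, batch_hook=None) -> TrainedModel:
    """Leave-one-patient-out training over every slice of the other patients.

    ``cohort`` is a sequence of objects with ``volume`` and ``labels``
    attributes (e.g. :class:`slicefill.phantom.CohortPatient`).
    """
    ids = list(range(len(cohort)))
    if exclude_patient not in ids:
        raise ValueError(f"unknown patient id {exclude_patient}")
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 patients")
    images, labels, keys = [], [], []
    for pid in ids:
        if pid == exclude_patient:
            continue
        vol = _normalize(cohort[pid].volume.data, cfg.normalization)
        for s in range(vol.shape[0]):
            images.append(vol[s])
            labels.append(cohort[pid].labels.labels[s])
            keys.append((pid, s))
    if not images:
        raise ValueError("empty training set")
    return _train(np.stack(images), np.stack(labels).astype(np.int64), keys,
                  spec, cfg, batch_hook)


def train_ov2assion(volume: Volume, sparse: SparseLabelMap, spec: NetworkSpec,
                    cfg: TrainConfig, batch_hook=None) -> TrainedModel:
    """Per-volume training on the manually annotated sections only.

    The withheld sections never contribute to the loss; the model is meant
    to overfit this single patient's anatomy and complete the gaps.
    """
    if volume.shape != sparse.shape:
        raise ShapeMismatchError(
            f"volume {volume.shape} vs sparse labels {sparse.shape}")
    manual_idx = sparse.schedule.manual_indices
    if manual_idx.size < 2:
        raise ScheduleError("need at least 2 manual slices to train")
    x = _normalize(volume.data, cfg.normalization)
    images = x[manual_idx]
    labels = sparse.labels[manual_idx].astype(np.int64)
    keys = [(0, int(s)) for s in manual_idx]
    return _train(images, labels, keys, spec, cfg, batch_hook)


def complete(model: TrainedModel, volume: Volume, sparse: SparseLabelMap) -> LabelMap:
    """Complete the withheld sections; manual sections are copied verbatim."""
    if volume.shape != sparse.shape:
        raise ShapeMismatchError(
            f"volume {volume.shape} vs sparse labels {sparse.shape}")
    pred = model.predict_volume(volume)
    out = pred.labels.copy()
    out[sparse.schedule.manual] = sparse.labels[sparse.schedule.manual]
    return LabelMap(out, volume.spacing)
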