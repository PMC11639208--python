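"""Two-stage orchestration: stage-1 training, stage-2 training-free counting.

Stage 1 trains the projection heads of the similarity comparison module, the
enhancement block, and the density decoder with Adam on the density MSE
loss, while the image encoder and the whole support (prototype) path stay
frozen.  Stage 2 performs inference with *all* parameters frozen: exemplar
boxes on a novel crop supply the prototypes, and the count is the sum of the
decoded density map.  Parameter checksums make both freezing contracts
testable.

Also home to the dataset manifest readers, the checkpoint format, and the
configuration dataclasses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.transform import resize as sk_resize

from ._autograd import Tensor, as_tensor
from .densityhead import (DecoderParams, DensityMap, decode_t, gt_density,
                          init_decoder_params, mse_loss_t)
from .encoding import extract_features, get_extractor
from .enhancement import (EnhanceParams, init_enhance_params, msfem_iterate_t)
from .evalmetrics import CountReport
from .fixtures import AnnotatedField
from .matching import MappingParams, init_mapping_params
from .rve import PrototypeSet, build_prototypes

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CountingModel",
    "Adam",
    "toy_model_config",
    "toy_train_config",
    "train_stage1",
    "infer_stage2",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "read_manifest",
    "load_field",
    "param_checksum",
]

CHECKPOINT_FORMAT = "headcount-checkpoint-v1"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    image_size: int = 512
    feature_size: int = 128
    backbone_channels: int = 64
    projected_channels: int = 256
    scales: tuple[int, ...] = (1, 3, 5)
    n_iterations: int = 2
    extractor: str = "toy"
    mask_provider: str = "otsu"
    use_mask_refinement: bool = True
    multiscale: bool = True
    spatial_attention: bool = True
    conv_attention: bool = True
    shared_mapping: bool = False
    logit_scale: str = "product"
    seed: int = 0

    def __post_init__(self):
        self.scales = tuple(self.scales)
        if self.image_size != 4 * self.feature_size:
            raise ValueError(
                f"image_size must be 4 x feature_size, got "
                f"{self.image_size} vs {self.feature_size}"
            )
        if any(k % 2 == 0 for k in self.scales) or list(self.scales) != sorted(
            set(self.scales)
        ):
            raise ValueError(f"scales must be odd and strictly ascending: {self.scales}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def effective_scales(self) -> tuple[int, ...]:
        """Single-scale ablation runs the middle (3x3) prototype only."""
        return self.scales if self.multiscale else (3,)

    @property
    def effective_mask_provider(self) -> str:
        return self.mask_provider if self.use_mask_refinement else "boxfill"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 2e-5
    decay_factor: float = 0.25
    decay_every: int = 80
    epochs: int = 200
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Step-decay schedule; `epoch` is 0-based."""
        return self.learning_rate * self.decay_factor ** (epoch // self.decay_every)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def toy_model_config(**overrides) -> ModelConfig:
    """Desk-scale configuration: 64x64 images, 16x16 features, 32 channels."""
    base = dict(image_size=64, feature_size=16, backbone_channels=32,
                projected_channels=32, n_iterations=1, extractor="toy",
                mask_provider="boxfill")
    base.update(overrides)
    return ModelConfig(**base)


def toy_train_config(**overrides) -> TrainConfig:
    """Training settings for the desk-scale study: Adam at its canonical
    1e-3 default, decay interval keeping the 80-of-200 epoch ratio."""
    base = dict(learning_rate=1e-3, decay_every=12, epochs=30, batch_size=1)
    base.update(overrides)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def param_checksum(named: dict[str, Tensor]) -> str:
    h = hashlib.sha256()
    for name in sorted(named):
        h.update(name.encode())
        h.update(np.ascontiguousarray(named[name].data, dtype=np.float64).tobytes())
    return h.hexdigest()


class CountingModel:
    """Frozen encoder + frozen prototype path + trainable interaction/decoder."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.extractor = get_extractor(config.extractor,
                                       channels=config.backbone_channels,
                                       seed=config.seed)
        rng = np.random.default_rng(config.seed)
        scales = config.effective_scales
        c = self.extractor.channels
        self.mapping: MappingParams = init_mapping_params(
            c, config.projected_channels, scales, rng,
            shared=config.shared_mapping)
        self.mapping.logit_scale = config.logit_scale
        self.enhance: EnhanceParams = init_enhance_params(
            c, scales, rng, n_iterations=config.n_iterations,
            multiscale=config.multiscale,
            use_spatial_attention=config.spatial_attention,
            use_conv_attention=config.conv_attention)
        self.decoder: DecoderParams = init_decoder_params(c, rng)

    # -- parameters ----------------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out = {}
        out.update(self.mapping.named_parameters())
        out.update(self.enhance.named_parameters())
        out.update(self.decoder.named_parameters())
        return out

    def trainable_checksum(self) -> str:
        return param_checksum(self.named_parameters())

    def encoder_checksum(self) -> str:
        return self.extractor.parameter_checksum()

    # -- forward -------------------------------------------------------------
    def build_prototypes(self, support_image: np.ndarray, boxes) -> PrototypeSet:
        return build_prototypes(support_image, boxes, self.extractor,
                                mask_provider=self.config.effective_mask_provider,
                                scales=self.config.effective_scales)

    def encode(self, image: np.ndarray) -> np.ndarray:
        return extract_features(image, self.extractor).values

    def forward_t(self, fq_values: np.ndarray, protos: PrototypeSet) -> Tensor:
        fp = msfem_iterate_t(as_tensor(fq_values), protos.prototypes,
                             self.mapping, self.enhance,
                             self.config.effective_scales)
        return decode_t(fp, self.decoder)

    def predict(self, image: np.ndarray, boxes) -> DensityMap:
        if len(boxes) < 1:
            raise ValueError("at least one exemplar required")
        protos = self.build_prototypes(image, boxes)
        density = self.forward_t(self.encode(image), protos)
        return DensityMap(values=density.data)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def read_manifest(path) -> tuple[list[dict], Path]:
    """Load a dataset manifest; returns (records, base directory)."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    records = doc.get("records", [])
    for rec in records:
        for key in ("image", "points"):
            if not (path.parent / rec[key]).exists():
                raise FileNotFoundError(f"manifest references missing file {rec[key]}")
    return records, path.parent


def load_field(record: dict, base: Path) -> AnnotatedField:
    """Materialize one manifest record as an in-memory annotated field."""
    img = np.asarray(Image.open(base / record["image"]).convert("RGB"),
                     dtype=np.float64) / 255.0
    pts_df = pd.read_csv(base / record["points"], float_precision="round_trip")
    points = [(float(x), float(y)) for x, y in zip(pts_df["x"], pts_df["y"])]
    boxes = [list(map(int, b)) for b in record["boxes"]]
    masks = []
    for mp in record.get("masks") or []:
        m = np.asarray(Image.open(base / mp), dtype=np.uint8)
        masks.append((m > 0).astype(np.uint8))
    return AnnotatedField(image=img, points=points, boxes=boxes, masks=masks,
                          count=len(points))


def _as_fields(manifest) -> list[AnnotatedField]:
    if isinstance(manifest, (str, Path)):
        records, base = read_manifest(manifest)
        return [load_field(r, base) for r in records]
    return list(manifest)


# ---------------------------------------------------------------------------
# stage 1: training
# ---------------------------------------------------------------------------

def train_stage1(manifest, model_cfg: ModelConfig | CountingModel,
                 train_cfg: TrainConfig, log_path=None,
                 checkpoint_path=None) -> tuple["CountingModel", list[dict]]:
    """Train mapping/enhancement/decoder parameters on density MSE.

    `manifest` is a manifest path or a list of AnnotatedField.  The encoder
    and the prototype path receive no updates; per-record query features,
    prototypes, and ground-truth densities are precomputed once (they are
    frozen quantities).  Returns the trained model and the per-epoch history
    ``[{"epoch", "loss", "lr"}, ...]``, also written as JSON-lines if
    `log_path` is given.
    """
    fields = _as_fields(manifest)
    if not fields:
        raise ValueError("empty training manifest")
    model = (model_cfg if isinstance(model_cfg, CountingModel)
             else CountingModel(model_cfg))
    cfg = model.config

    encoder_before = model.encoder_checksum()
    cache = []
    for f in fields:
        if f.image.shape[0] != cfg.image_size or f.image.shape[1] != cfg.image_size:
            raise ValueError(
                f"training image is {f.image.shape[:2]}, model expects "
                f"{cfg.image_size}x{cfg.image_size}"
            )
        fq = model.encode(f.image)
        protos = model.build_prototypes(f.image, f.boxes)
        dgt = gt_density(f.points, (cfg.image_size, cfg.image_size)).values
        cache.append((fq, protos, dgt))

    params = model.named_parameters()
    opt = Adam(params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(train_cfg.epochs):
            opt.lr = train_cfg.lr_at(epoch)
            order = rng.permutation(len(cache))
            losses = []
            for start in range(0, len(order), train_cfg.batch_size):
                idx = order[start:start + train_cfg.batch_size]
                opt.zero_grad()
                preds, targets = [], []
                for i in idx:
                    fq, protos, dgt = cache[i]
                    preds.append(model.forward_t(fq, protos))
                    targets.append(dgt)
                loss = mse_loss_t(preds, targets)
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                     "lr": opt.lr, "seed": train_cfg.seed}
            history.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()

    assert model.encoder_checksum() == encoder_before, \
        "frozen encoder was modified during training"
    if checkpoint_path is not None:
        save_checkpoint(model, train_cfg, checkpoint_path)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CountingModel, train_cfg: TrainConfig | None,
                    path) -> None:
    meta = {
        "format": CHECKPOINT_FORMAT,
        "model_config": model.config.to_dict(),
        "train_config": train_cfg.to_dict() if train_cfg else None,
        "seed": model.config.seed,
    }
    arrays = {f"param::{k}": p.data for k, p in model.named_parameters().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> CountingModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        model = CountingModel(ModelConfig.from_dict(meta["model_config"]))
        params = model.named_parameters()
        for key in archive.files:
            if key.startswith("param::"):
                name = key[len("param::"):]
                if name not in params:
                    raise ValueError(f"checkpoint parameter {name} not in model")
                params[name].data = archive[key].astype(np.float64)
    return model


# ---------------------------------------------------------------------------
# stage 2: inference and evaluation
# ---------------------------------------------------------------------------

def infer_stage2(image: np.ndarray, boxes,
                 model: CountingModel | str | Path) -> DensityMap:
    """Training-free counting of a novel crop from 1..k exemplar boxes.

    Arbitrary-size images are bilinearly resized to the model's input size
    (boxes rescaled along), and the density map is resized back with its
    mass renormalized, so the count is invariant to the resize.
    """
    if isinstance(model, (str, Path)):
        model = load_checkpoint(model)
    if len(boxes) < 1:
        raise ValueError("at least one exemplar required")
    rows, cols = image.shape[:2]
    size = model.config.image_size
    if (rows, cols) == (size, size):
        return model.predict(image, boxes)
    sy, sx = size / rows, size / cols
    resized = sk_resize(image, (size, size), order=1, preserve_range=True,
                        anti_aliasing=False)
    scaled_boxes = []
    for x0, y0, x1, y1 in boxes:
        sb = [int(np.floor(x0 * sx)), int(np.floor(y0 * sy)),
              int(np.ceil(x1 * sx)), int(np.ceil(y1 * sy))]
        sb[2], sb[3] = min(max(sb[2], sb[0] + 1), size), min(max(sb[3], sb[1] + 1), size)
        scaled_boxes.append(sb)
    dm = model.predict(resized, scaled_boxes)
    back = sk_resize(dm.values, (rows, cols), order=1, preserve_range=True,
                     anti_aliasing=False)
    back = np.maximum(back, 0.0)
    if back.sum() > 0:
        back *= dm.count / back.sum()  # preserve density mass across resize
    return DensityMap(values=back)


def evaluate(manifest, model: CountingModel | str | Path,
             report_json=None, report_csv=None) -> CountReport:
    """Run stage-2 inference over a manifest and aggregate counting metrics."""
    if isinstance(model, (str, Path)):
        model = load_checkpoint(model)
    fields = _as_fields(manifest)
    if not fields:
        raise ValueError("empty evaluation manifest")
    before = model.trainable_checksum()
    preds, truths = [], []
    for f in fields:
        dm = infer_stage2(f.image, f.boxes, model)
        preds.append(dm.count)
        truths.append(float(f.count))
    assert model.trainable_checksum() == before, \
        "inference modified model parameters"
    report = CountReport.from_counts(preds, truths)
    if report_json:
        report.to_json(report_json)
    if report_csv:
        report.to_csv(report_csv)
    return report
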