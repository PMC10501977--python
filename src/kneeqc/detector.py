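"""Multiresolution heatmap-regression detector for knee landmarks.

The architecture follows the high-resolution-network (HR-Net) design: a stem
of two stride-2 3x3 convolutions brings the input to 1/4 resolution; four
stages run parallel branches at 1/4, 1/8, 1/16 and 1/32 resolution with
channel widths C, 2C, 4C, 8C; every convolution is a conv-BN-ReLU block;
exchange blocks repeatedly fuse all branches (stride-2 3x3 convolutions
downward, nearest-neighbor upsampling plus 1x1 convolution upward, averaged
per output branch); the head lifts branches 2-4
back to branch-1 resolution with 1x1 convolutions, concatenates, and maps to
nine output channels — one Gaussian heatmap per landmark.

Two presets are provided: ``full`` (C=32, input short side 288, exchange
repeats 1/4/3 in stages 2-4) and ``tiny`` (C=8, input 64, exchange repeats
capped at 2), the latter sized so that training and inference run in minutes
on a single CPU against the synthetic phantoms.  Networks train from seeded
He-style random initialization with SGD (momentum, weight decay, stepped
learning-rate decay) on a mean-squared-error heatmap loss; the four
LAT-only channels regress to zero on AP images rather than being masked.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .geometry import Keypoint, KeypointSet, Point2D
from .heatmaps import HeatmapStack, encode_heatmaps
from .nn import autograd as ag

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainedModel",
    "build_network",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "prepare_input",
]

N_KEYPOINTS = 9


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Branch ``r`` (1-based) carries ``base_channels * 2**(r-1)`` channels at
    1/4 / 1/8 / 1/16 / 1/32 of the input resolution.
    """

    base_channels: int = 32
    stage_exchange_counts: tuple[int, int, int] = (1, 4, 3)
    stem_stride: int = 4
    out_channels: int = N_KEYPOINTS
    input_short_side: int = 288
    upsample_mode: str = "nearest"  # or "bilinear" (nearest is the HR-Net default)
    scale_preset: str = "full"

    def __post_init__(self) -> None:
        if self.out_channels != N_KEYPOINTS:
            raise ValueError(f"out_channels must be {N_KEYPOINTS}")
        if self.stem_stride != 4:
            raise ValueError("the stem is two stride-2 convolutions (stride 4)")
        if len(self.stage_exchange_counts) != 3 or min(self.stage_exchange_counts) < 1:
            raise ValueError("stage_exchange_counts must be three positive ints")

    @property
    def branch_channels(self) -> tuple[int, int, int, int]:
        return tuple(self.base_channels * 2**r for r in range(4))

    @classmethod
    def full(cls) -> "NetworkConfig":
        return cls()

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        """CPU-scale preset: C=8, 64-px input, exchange repeats capped at 2."""
        return cls(
            base_channels=8,
            stage_exchange_counts=(1, 2, 2),
            input_short_side=64,
            scale_preset="tiny",
        )


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule; defaults follow the full-scale HR-Net-style recipe."""

    lr: float = 0.002
    lr_decay_factor: float = 0.1
    lr_decay_epochs: tuple[int, ...] = (50, 56)
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 60
    flip_prob: float = 0.5
    inversion_prob: float = 0.5
    heatmap_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("invalid training hyperparameters")
        if self.lr_decay_epochs and max(self.lr_decay_epochs) >= max(self.epochs, 1):
            # decay milestones past the end are silently inert; forbid them
            raise ValueError("lr decay epochs must lie before the final epoch")

    @classmethod
    def tiny(cls, seed: int = 0, epochs: int = 30) -> "TrainConfig":
        """Schedule for the tiny preset: higher lr (mean-MSE gradients are
        tiny at this scale), decay at 2/3 and 5/6 of the run."""
        return cls(
            lr=1.0,
            lr_decay_epochs=(int(epochs * 2 / 3), int(epochs * 5 / 6)),
            epochs=epochs,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# parameter store and forward graph


def _he_conv(rng: np.random.Generator, o: int, c: int, k: int) -> ag.Parameter:
    std = np.sqrt(2.0 / (c * k * k))
    return ag.Parameter(rng.normal(0.0, std, size=(o, c, k, k)).astype(np.float32))


class TrainedModel:
    """Architecture + weights + training log.

    ``predict`` on any valid input returns a 9-channel :class:`HeatmapStack`.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, ag.Parameter] = {}
        self.buffers: dict[str, np.ndarray] = {}  # batch-norm running stats
        self.training_log: list[dict] = []
        self._init_params(np.random.default_rng(seed))

    # -- construction -------------------------------------------------------

    def _conv(self, rng, name: str, o: int, c: int, k: int, bn: bool = True) -> None:
        self.params[f"{name}.w"] = _he_conv(rng, o, c, k)
        self.params[f"{name}.b"] = ag.Parameter(np.zeros(o, dtype=np.float32))
        if bn:  # conv -> batch norm -> ReLU, the standard HR-Net block
            self.params[f"{name}.g"] = ag.Parameter(np.ones(o, dtype=np.float32))
            self.params[f"{name}.bt"] = ag.Parameter(np.zeros(o, dtype=np.float32))
            self.buffers[f"{name}.rm"] = np.zeros(o, dtype=np.float64)
            self.buffers[f"{name}.rv"] = np.ones(o, dtype=np.float64)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        ch = cfg.branch_channels
        self._conv(rng, "stem.c1", ch[0], 1, 3)
        self._conv(rng, "stem.c2", ch[0], ch[0], 3)
        self._conv(rng, "stage1.block", ch[0], ch[0], 3)
        # transitions: new branch r+1 from branch r, stride 2, doubled width
        for s in (2, 3, 4):
            self._conv(rng, f"trans{s}", ch[s - 1], ch[s - 2], 3)
        # exchange blocks per stage
        for s, n_ex in zip((2, 3, 4), cfg.stage_exchange_counts):
            nb = s  # stage s has s branches
            for e in range(n_ex):
                for r in range(nb):
                    self._conv(rng, f"s{s}.e{e}.branch{r}", ch[r], ch[r], 3)
                for r in range(nb):  # fusion paths q -> r
                    for q in range(nb):
                        if q == r:
                            continue
                        if q < r:  # downsample chain
                            for d in range(r - q):
                                cin = ch[q] if d == 0 else ch[r]
                                self._conv(rng, f"s{s}.e{e}.down{q}to{r}.{d}", ch[r], cin, 3)
                        else:  # upsample: 1x1 conv then resize
                            self._conv(rng, f"s{s}.e{e}.up{q}to{r}", ch[r], ch[q], 1)
        # head: per-branch 1x1 to C, concat, final 1x1 to 9
        for r in range(4):
            self._conv(rng, f"head.lat{r}", ch[0], ch[r], 1)
        self._conv(rng, "head.final", cfg.out_channels, 4 * ch[0], 1, bn=False)
        # zero-init the output conv: training starts from the all-zero heatmap
        self.params["head.final.w"].data[:] = 0.0

    # -- forward -------------------------------------------------------------

    def _apply(
        self, name: str, x: ag.Tensor, stride: int = 1, pad: int | None = None, training: bool = False
    ) -> ag.Tensor:
        w = self.params[f"{name}.w"]
        k = w.data.shape[-1]
        out = ag.conv2d(x, w, self.params[f"{name}.b"], stride=stride, pad=(k // 2 if pad is None else pad))
        if f"{name}.g" in self.params:
            out = ag.batch_norm(
                out,
                self.params[f"{name}.g"],
                self.params[f"{name}.bt"],
                self.buffers[f"{name}.rm"],
                self.buffers[f"{name}.rv"],
                training=training,
            )
        return out

    def forward(self, x: ag.Tensor, training: bool = False) -> ag.Tensor:
        cfg = self.config
        h = ag.relu(self._apply("stem.c1", x, stride=2, training=training))
        h = ag.relu(self._apply("stem.c2", h, stride=2, training=training))
        branches = [ag.relu(self._apply("stage1.block", h, training=training))]
        for s, n_ex in zip((2, 3, 4), cfg.stage_exchange_counts):
            branches.append(ag.relu(self._apply(f"trans{s}", branches[-1], stride=2, training=training)))
            for e in range(n_ex):
                branches = self._exchange(s, e, branches, training)
        # head
        lifted = []
        for r, br in enumerate(branches):
            t = self._apply(f"head.lat{r}", br, training=training)
            if r > 0:
                t = self._upsample(t, 2**r)
            lifted.append(ag.relu(t))
        return self._apply("head.final", ag.concat(lifted))

    def _upsample(self, t: ag.Tensor, factor: int) -> ag.Tensor:
        if self.config.upsample_mode == "bilinear":
            return ag.upsample_bilinear(t, factor)
        return ag.upsample_nearest(t, factor)

    def _exchange(self, s: int, e: int, branches: list[ag.Tensor], training: bool) -> list[ag.Tensor]:
        nb = len(branches)
        feats = [
            ag.relu(self._apply(f"s{s}.e{e}.branch{r}", br, training=training))
            for r, br in enumerate(branches)
        ]
        out: list[ag.Tensor] = []
        for r in range(nb):
            acc = feats[r]
            for q in range(nb):
                if q == r:
                    continue
                if q < r:
                    t = feats[q]
                    for d in range(r - q):
                        t = self._apply(f"s{s}.e{e}.down{q}to{r}.{d}", t, stride=2, training=training)
                else:
                    t = self._apply(f"s{s}.e{e}.up{q}to{r}", feats[q], training=training)
                    t = self._upsample(t, 2 ** (q - r))
                acc = ag.add(acc, t)
            # average the fused contributions to keep activation variance flat
            out.append(ag.relu(ag.scale(acc, 1.0 / nb)))
        return out

    # -- convenience ---------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.params.items()}
        state.update({f"buf:{k}": v.copy() for k, v in self.buffers.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=np.float32)
        for k in self.buffers:
            self.buffers[k] = np.asarray(state[f"buf:{k}"], dtype=np.float64)


def build_network(cfg: NetworkConfig, seed: int = 0) -> TrainedModel:
    """An untrained network with seeded He-style initialization."""
    return TrainedModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# input preparation


def _pad_to_multiple(img: np.ndarray, mult: int = 32) -> np.ndarray:
    h, w = img.shape
    ph, pw = (-h) % mult, (-w) % mult
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    return img


def prepare_input(image: np.ndarray, cfg: NetworkConfig) -> tuple[np.ndarray, float]:
    """Resize the short side to the network's input size and pad to /32.

    Returns the network-ready array and the scale factor mapping network
    coordinates back to the original image (original = network * 1/scale).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    short = min(img.shape)
    scale = cfg.input_short_side / short
    if scale != 1.0:
        new_shape = (round(img.shape[0] * scale), round(img.shape[1] * scale))
        img = _sk_resize(img, new_shape, order=1, anti_aliasing=scale < 1.0)
    return _pad_to_multiple(img), scale


# ---------------------------------------------------------------------------
# training


def _augment(
    img: np.ndarray, kps: KeypointSet, rng: np.random.Generator, cfg: TrainConfig
) -> tuple[np.ndarray, KeypointSet]:
    # horizontal flip: x -> W-1-x; the 9 labels have no left/right pairs, so
    # no label swapping is needed.  Intensity inversion leaves keypoints alone.
    if rng.uniform() < cfg.flip_prob:
        img = img[:, ::-1].copy()
        w = img.shape[1]
        kps = KeypointSet(
            view=kps.view,
            keypoints={
                lab: Keypoint(lab, Point2D(w - 1 - kp.position.x, kp.position.y), kp.visible)
                for lab, kp in kps.keypoints.items()
            },
        )
    if rng.uniform() < cfg.inversion_prob:
        img = 1.0 - img
    return img, kps


def _scale_keypoints(kps: KeypointSet, scale: float) -> KeypointSet:
    if scale == 1.0:
        return kps
    return KeypointSet(
        view=kps.view,
        keypoints={
            lab: Keypoint(lab, Point2D(kp.position.x * scale, kp.position.y * scale), kp.visible)
            for lab, kp in kps.keypoints.items()
        },
    )


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def train(
    model: TrainedModel,
    dataset: Sequence[tuple[np.ndarray, KeypointSet]],
    cfg: TrainConfig,
) -> TrainedModel:
    """SGD training on Gaussian heatmap targets; fully seeded.

    The loss is the mean per-pixel squared error over all nine channels;
    channels of absent keypoints (F-I on AP images) regress toward zero.
    ``epochs=0`` returns the model unchanged.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    net_cfg = model.config
    stride = net_cfg.stem_stride

    prepared: list[tuple[np.ndarray, KeypointSet]] = []
    for img, kps in dataset:
        net_img, scale = prepare_input(img, net_cfg)
        prepared.append((net_img, _scale_keypoints(kps, scale)))

    velocity = {k: np.zeros_like(p.data) for k, p in model.params.items()}
    lr = cfg.lr
    n = len(prepared)
    for epoch in range(cfg.epochs):
        if epoch in cfg.lr_decay_epochs:
            lr *= cfg.lr_decay_factor
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, targets = [], []
            for i in idx:
                img, kps = _augment(prepared[i][0], prepared[i][1], rng, cfg)
                hshape = (img.shape[0] // stride, img.shape[1] // stride)
                targets.append(
                    encode_heatmaps(kps, hshape, stride=stride, sigma=cfg.heatmap_sigma).maps
                )
                imgs.append(img)
            x = ag.Tensor(np.stack(imgs)[:, None].astype(np.float32))
            y = np.stack(targets).astype(np.float32)
            loss = ag.mse_loss(model.forward(x, training=True), y)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            for k, p in model.params.items():
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                g = g + cfg.weight_decay * p.data
                velocity[k] = cfg.momentum * velocity[k] - lr * g
                p.data += velocity[k]
                p.grad = None
            epoch_loss += float(loss.data)
            n_batches += 1
        model.training_log.append({"epoch": epoch, "loss": epoch_loss / n_batches, "lr": lr})
    return model


# ---------------------------------------------------------------------------
# inference and persistence


def predict(model: TrainedModel, image: np.ndarray) -> HeatmapStack:
    """Heatmaps for one preprocessed grayscale image in [0, 1].

    The image is taken at its given size (padded to a multiple of 32); the
    returned stack's stride refers to these padded-input pixels.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if min(img.shape) < model.config.stem_stride * 8:
        raise ValueError(f"image {img.shape} smaller than the stem requires")
    img = _pad_to_multiple(img)
    x = ag.Tensor(img[None, None].astype(np.float32))
    out = model.forward(x)
    return HeatmapStack(maps=np.maximum(out.data[0], 0.0), stride=model.config.stem_stride)


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Single-file archive: config JSON + weights + training log."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("config.json", json.dumps(asdict(model.config)))
        zf.writestr("training_log.json", json.dumps(model.training_log))
        buf = _io.BytesIO()
        np.savez(buf, **model.state_dict())
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(Path(path)) as zf:
        cfg_raw = json.loads(zf.read("config.json"))
        cfg_raw["stage_exchange_counts"] = tuple(cfg_raw["stage_exchange_counts"])
        cfg = NetworkConfig(**cfg_raw)
        model = TrainedModel(cfg, seed=0)
        with zf.open("weights.npz") as fh:
            state = dict(np.load(_io.BytesIO(fh.read())))
        model.load_state_dict(state)
        model.training_log = json.loads(zf.read("training_log.json"))
    return model
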