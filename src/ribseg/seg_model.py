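"""Configurable 2-D/3-D U-Net segmenter with patch sampling and training.

The architecture follows the adaptive-U-Net recipe: an encoder–decoder with
skip connections, two (conv – instance-norm – leaky-ReLU) units per
resolution level, per-axis pooling counts (so anisotropic patches pool only
where resolution permits), nearest-neighbour upsampling, and a sigmoid head
producing a per-voxel foreground probability.  The cascade variant trains a
coarse model on low-resolution volumes and a fine model that receives the
upsampled coarse probability as a second input channel.

Full-size configurations are shipped as presets (``published_2d``,
``published_3d_lowres``, ``published_3d_fullres``); the ``tiny_3d`` preset is the
desk-scale workhorse used throughout the test-bed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .geometry import BinaryMask, ImageVolume
from .losses import LossConfig, LossValues, total_loss, total_loss_grad
from .preprocess import resample

MAX_CHANNELS = 320


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of one segmenter.

    ``pools_per_axis`` gives the number of 2x downsamplings per axis; an
    axis stops pooling once its own count is exhausted, which is how
    anisotropic patches like 96x160x160 with pools [4, 5, 5] are handled.
    Normalization is instance norm and the nonlinearity is leaky ReLU
    throughout; both are fixed, only the slope is configurable.
    """

    dims: int = 3
    patch_size: tuple[int, ...] = (32, 32, 32)
    pools_per_axis: tuple[int, ...] = (2, 2, 2)
    base_channels: int = 8
    negative_slope: float = 0.01
    norm: str = "instance"

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch_size", tuple(int(p) for p in self.patch_size))
        object.__setattr__(self, "pools_per_axis", tuple(int(p) for p in self.pools_per_axis))
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if len(self.patch_size) != self.dims or len(self.pools_per_axis) != self.dims:
            raise ValueError("patch_size and pools_per_axis rank must equal dims")
        if self.norm != "instance":
            raise ValueError("only instance normalization is supported")
        for p, k in zip(self.patch_size, self.pools_per_axis):
            if p % (2**k) != 0:
                raise ValueError(
                    f"patch axis {p} not divisible by 2^{k}; adjust patch_size/pools"
                )

    @property
    def n_levels(self) -> int:
        return max(self.pools_per_axis) + 1

    def level_factors(self, level: int) -> tuple[int, ...]:
        """Pooling factors applied between ``level`` and ``level + 1``."""
        return tuple(2 if level < k else 1 for k in self.pools_per_axis)


PRESETS: dict[str, UNetConfig] = {
    "published_2d": UNetConfig(dims=2, patch_size=(512, 512), pools_per_axis=(7, 7),
                           base_channels=32),
    "published_3d_lowres": UNetConfig(dims=3, patch_size=(96, 160, 160),
                                  pools_per_axis=(4, 5, 5), base_channels=32),
    "published_3d_fullres": UNetConfig(dims=3, patch_size=(96, 160, 160),
                                   pools_per_axis=(4, 5, 5), base_channels=32),
    "tiny_3d": UNetConfig(dims=3, patch_size=(32, 32, 32),
                          pools_per_axis=(2, 2, 2), base_channels=8),
    "tiny_2d": UNetConfig(dims=2, patch_size=(32, 32), pools_per_axis=(2, 2),
                          base_channels=8),
}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 2
    epochs: int = 10
    learning_rate: float = 1e-2
    fg_patch_fraction: float = 0.5
    seed: int = 0
    steps_per_epoch: int | None = None  # default: one step per dataset sample
    grad_clip: float = 5.0  # global gradient-norm cap; 0 disables

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.fg_patch_fraction <= 1.0:
            raise ValueError("fg_patch_fraction must lie in [0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class CascadeConfig:
    coarse_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    coarse: UNetConfig = field(default_factory=lambda: PRESETS["tiny_3d"])
    fine: UNetConfig = field(default_factory=lambda: PRESETS["tiny_3d"])


class UNet:
    """Encoder–decoder segmentation operator.

    ``forward``/``backward`` run on batches ``(N, C, *patch)``;
    :meth:`predict` is the single-patch convenience used by sliding-window
    inference.
    """

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        self.cfg = cfg
        self.in_channels = in_channels
        L = cfg.n_levels
        ch = [min(cfg.base_channels * 2**i, MAX_CHANNELS) for i in range(L)]
        self.channels = ch
        self.enc = []
        for i in range(L):
            c_in = in_channels if i == 0 else ch[i - 1]
            self.enc.append(nn.conv_block(cfg.dims, c_in, ch[i], rng, cfg.negative_slope))
        self.pools = [nn.MaxPool(cfg.level_factors(i)) for i in range(L - 1)]
        self.ups = [nn.Upsample(cfg.level_factors(i)) for i in range(L - 1)]
        self.dec = [
            nn.conv_block(cfg.dims, ch[i] + ch[i + 1], ch[i], rng, cfg.negative_slope)
            for i in range(L - 1)
        ]
        self.head = nn.Conv(cfg.dims, ch[0], 1, 1, rng)
        self.out_act = nn.Sigmoid()
        self._skip_channels = ch

    @property
    def patch_size(self) -> tuple[int, ...]:
        return self.cfg.patch_size

    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for block in self.enc + self.dec:
            params.extend(block.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        L = self.cfg.n_levels
        skips = []
        h = x.astype(np.float32)
        for i in range(L - 1):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.pools[i].forward(h)
        h = self.enc[L - 1].forward(h)
        for i in reversed(range(L - 1)):
            h = self.ups[i].forward(h)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h)
        return self.out_act.forward(self.head.forward(h))

    def backward(self, dp: np.ndarray) -> None:
        L = self.cfg.n_levels
        dh = self.head.backward(self.out_act.backward(dp.astype(np.float32)))
        dskips: list[np.ndarray | None] = [None] * (L - 1)
        for i in range(L - 1):
            dh = self.dec[i].backward(dh)
            c = self._skip_channels[i]
            dskips[i] = dh[:, :c]
            dh = self.ups[i].backward(np.ascontiguousarray(dh[:, c:]))
        dh = self.enc[L - 1].backward(dh)
        for i in reversed(range(L - 1)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Probability map for one patch of shape ``patch_size`` (or with a
        leading channel axis for multi-channel inputs)."""
        arr = np.asarray(patch, dtype=np.float32)
        if arr.ndim == self.cfg.dims:
            arr = arr[None]
        if arr.shape[0] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {arr.shape[0]}"
            )
        return self.forward(arr[None])[0, 0]


def build_segmenter(cfg: UNetConfig, seed: int = 0, in_channels: int = 1) -> UNet:
    """Construct a seeded, untrained segmentation operator."""
    return UNet(cfg, np.random.default_rng(seed), in_channels=in_channels)


def _image_array(image) -> np.ndarray:
    arr = image.values if isinstance(image, ImageVolume) else np.asarray(image)
    return arr.astype(np.float32)


def _mask_array(mask) -> np.ndarray:
    arr = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    return arr.astype(np.float32)


def sample_patch(image, mask, patch_size: tuple[int, ...],
                 fg_fraction: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one co-located (image, mask) training patch.

    With probability ``fg_fraction`` the patch is centred on a uniformly
    chosen foreground voxel (clamped so the window stays inside the
    volume — the chosen voxel is always still covered); otherwise the
    origin is uniform over the valid range.  Volumes smaller than the
    patch are padded with the image minimum / mask 0.  For a 2-D patch on
    a 3-D volume, an axial slice is drawn first.
    """
    img = _image_array(image)
    msk = _mask_array(mask)
    ndim = len(patch_size)
    channel_axis = img.ndim == msk.ndim + 1
    if msk.ndim == 3 and ndim == 2:
        fg = np.argwhere(msk > 0)
        if fg_fraction > 0 and len(fg) and rng.uniform() < fg_fraction:
            z = int(fg[rng.integers(len(fg))][0])
        else:
            z = int(rng.integers(msk.shape[0]))
        img = img[:, z] if channel_axis else img[z]
        msk = msk[z]

    pad_width = [(0, max(0, p - s)) for p, s in zip(patch_size, msk.shape)]
    if any(w[1] for w in pad_width):
        fill = float(img.min())
        img_pad = ([(0, 0)] if channel_axis else []) + pad_width
        img = np.pad(img, img_pad, constant_values=fill)
        msk = np.pad(msk, pad_width, constant_values=0.0)

    shape = msk.shape
    fg = np.argwhere(msk > 0)
    if fg_fraction > 0 and len(fg) and rng.uniform() < fg_fraction:
        centre = fg[rng.integers(len(fg))]
        origin = [
            int(np.clip(c - p // 2, 0, s - p))
            for c, p, s in zip(centre, patch_size, shape)
        ]
    else:
        origin = [int(rng.integers(0, s - p + 1)) for p, s in zip(patch_size, shape)]
    window = tuple(slice(o, o + p) for o, p in zip(origin, patch_size))
    img_window = ((slice(None),) + window) if channel_axis else window
    return img[img_window].copy(), msk[window].copy()


def _mean_losses(vals: list[LossValues]) -> LossValues:
    return LossValues(
        l_dice=float(np.mean([v.l_dice for v in vals])),
        l_ce=float(np.mean([v.l_ce for v in vals])),
        l_contour=float(np.mean([v.l_contour for v in vals])),
        total=float(np.mean([v.total for v in vals])),
    )


def train_segmenter(dataset, unet_cfg: UNetConfig, train_cfg: TrainConfig,
                    loss_cfg: LossConfig = LossConfig(), in_channels: int = 1,
                    net: UNet | None = None) -> tuple[UNet, list[LossValues]]:
    """Mini-batch training of the composite objective on sampled patches.

    ``dataset`` is a list of (image, mask) pairs (typed volumes or plain
    arrays; multi-channel images carry a leading channel axis).  Returns
    the operator holding the weights of the epoch with the lowest mean
    training loss (small batches make the last epochs noisy), plus the
    full per-epoch loss history.  Fully reproducible for a fixed seed.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if net is None:
        net = build_segmenter(unet_cfg, seed=train_cfg.seed, in_channels=in_channels)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed & 0x7FFFFFFF, 17]))
    params = net.parameters()
    opt = nn.Adam(params, lr=train_cfg.learning_rate)
    steps = train_cfg.steps_per_epoch or max(1, len(dataset))
    history: list[LossValues] = []
    best_loss = np.inf
    best_weights: list[np.ndarray] | None = None
    for epoch in range(train_cfg.epochs):
        epoch_vals: list[LossValues] = []
        for _ in range(steps):
            xs, ts = [], []
            for _ in range(train_cfg.batch_size):
                img, msk = dataset[rng.integers(len(dataset))]
                xp, tp = sample_patch(img, msk, unet_cfg.patch_size,
                                      train_cfg.fg_patch_fraction, rng)
                if xp.ndim == len(unet_cfg.patch_size):
                    xp = xp[None]
                xs.append(xp)
                ts.append(tp)
            x = np.stack(xs)
            p = net.forward(x)
            dp = np.zeros_like(p)
            batch_vals = []
            for i in range(len(ts)):
                vals = total_loss(p[i, 0], ts[i], loss_cfg)
                if not math.isfinite(vals.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {vals}"
                    )
                batch_vals.append(vals)
                dp[i, 0] = total_loss_grad(p[i, 0], ts[i], loss_cfg) / len(ts)
            opt.zero_grad()
            net.backward(dp)
            if train_cfg.grad_clip > 0:
                nn.clip_grad_norm(params, train_cfg.grad_clip)
            opt.step()
            epoch_vals.append(_mean_losses(batch_vals))
        epoch_mean = _mean_losses(epoch_vals)
        history.append(epoch_mean)
        if epoch_mean.total < best_loss:
            best_loss = epoch_mean.total
            best_weights = [p.value.copy() for p in params]
    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p.value[...] = w
    return net, history


class CascadeSegmenter:
    """Coarse low-resolution model + fine full-resolution model that takes
    the upsampled coarse probability as a second input channel."""

    def __init__(self, coarse: UNet, fine: UNet,
                 coarse_spacing_mm: tuple[float, float, float]):
        self.coarse = coarse
        self.fine = fine
        self.coarse_spacing_mm = tuple(float(s) for s in coarse_spacing_mm)

    def coarse_probability(self, image: ImageVolume, overlap: float = 0.5) -> np.ndarray:
        """Upsampled full-resolution coarse probability for one volume."""
        from . import inference  # local import: inference is operator-generic
        from scipy import ndimage

        low = resample(image, self.coarse_spacing_mm, mode="continuous")
        fused = inference.predict_volume_padded(self.coarse, low, overlap=overlap)
        zoom = np.asarray(image.geometry.size) / np.asarray(low.geometry.size)
        up = ndimage.zoom(fused.values, zoom, order=1, mode="nearest",
                          grid_mode=True, prefilter=False)
        up = up[tuple(slice(0, s) for s in image.geometry.size)]
        pad = [(0, t - s) for t, s in zip(image.geometry.size, up.shape)]
        if any(p[1] for p in pad):
            up = np.pad(up, pad, mode="edge")
        return np.clip(up, 0.0, 1.0).astype(np.float32)

    def predict_full(self, image: ImageVolume, overlap: float = 0.5):
        """Full-resolution fused probability of the whole cascade."""
        from . import inference
        from .geometry import ProbabilityVolume

        coarse_prob = self.coarse_probability(image, overlap)
        stacked = np.stack([image.values.astype(np.float32), coarse_prob])
        patch = self.fine.patch_size
        pad = [(0, max(0, p - s)) for p, s in zip(patch, image.geometry.size)]
        if any(p[1] for p in pad):
            fill = float(image.values.min())
            stacked = np.stack([
                np.pad(stacked[0], pad, constant_values=fill),
                np.pad(stacked[1], pad, constant_values=0.0),
            ])
        plan = inference.plan_windows(stacked.shape[1:], patch, overlap)
        fused = inference.predict_volume(self.fine, stacked, plan)
        values = fused.values[tuple(slice(0, s) for s in image.geometry.size)]
        return ProbabilityVolume(values=values, geometry=image.geometry)


def train_cascade(dataset: list[tuple[ImageVolume, BinaryMask]],
                  cascade_cfg: CascadeConfig, train_cfg: TrainConfig,
                  loss_cfg: LossConfig = LossConfig(),
                  return_history: bool = False):
    """Train the two-stage cascade on full-resolution (image, mask) pairs.

    The coarse model trains on volumes resampled to ``coarse_spacing_mm``;
    the fine model trains at full resolution with the coarse probability
    (upsampled back to the full grid) concatenated as an input channel.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    coarse_data = [
        (resample(img, cascade_cfg.coarse_spacing_mm, mode="continuous"),
         resample(msk, cascade_cfg.coarse_spacing_mm, mode="nearest"))
        for img, msk in dataset
    ]
    coarse, _ = train_segmenter(coarse_data, cascade_cfg.coarse, train_cfg, loss_cfg)
    helper = CascadeSegmenter(coarse, None, cascade_cfg.coarse_spacing_mm)
    fine_data = []
    for img, msk in dataset:
        prob = helper.coarse_probability(img)
        stacked = np.stack([img.values.astype(np.float32), prob])
        fine_data.append((stacked, msk))
    fine, fine_history = train_segmenter(fine_data, cascade_cfg.fine, train_cfg,
                                         loss_cfg, in_channels=2)
    if return_history:
        return coarse, fine, fine_history
    return coarse, fine


def save_segmenter(net: UNet, weights_path, config_path=None) -> None:
    """Persist weights as npz with a JSON sidecar of the architecture."""
    arrays = {f"p{i}": p.value for i, p in enumerate(net.parameters())}
    np.savez(weights_path, **arrays)
    if config_path is not None:
        with open(config_path, "w") as fh:
            json.dump({"config": asdict(net.cfg), "in_channels": net.in_channels}, fh, indent=2)


def load_segmenter(weights_path, config_path) -> UNet:
    with open(config_path) as fh:
        meta = json.load(fh)
    cfg = UNetConfig(**meta["config"])
    net = build_segmenter(cfg, in_channels=meta["in_channels"])
    data = np.load(weights_path)
    for i, p in enumerate(net.parameters()):
        p.value[...] = data[f"p{i}"]
    return net
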