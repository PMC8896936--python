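"""Stage-2 false-positive exclusion.

Three densely connected 3-D convolutional classifiers — one per crop size —
re-score every stage-1 candidate from nested local crops; their
probabilities are fused by a weighted average whose weights are the
per-size validation accuracies, so a size that classifies the validation
candidates better gets more say.  Candidates whose fused probability falls
below the decision threshold are the excluded false positives: stage 2 can
only ever remove candidates, never add them.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .geometry import BinaryMask
from .inference import CandidateRegion, MultiScaleCrops
from .seg_model import TrainConfig


class DegenerateLabelsError(ValueError):
    """Classifier training requires at least one positive and one negative."""


@dataclass(frozen=True)
class DenseNetConfig:
    """One crop-size classifier: dense blocks with ``growth_rate`` new
    channels per layer, 1x1x1 compression transitions with 2x pooling, a
    global-average-pooled single-logit head."""

    input_size: int = 32
    growth_rate: int = 8
    block_layout: tuple[int, ...] = (2, 2)
    compression: float = 0.5
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must lie in (0, 1]")
        n_pools = len(self.block_layout)  # stem pool + one per transition
        if self.input_size % (2**n_pools) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^{n_pools}"
            )


@dataclass(frozen=True)
class FusionWeights:
    """Per-size fusion weights: the validation accuracy of each crop-size
    classifier."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        for lam in (self.lambda1, self.lambda2, self.lambda3):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"fusion weights must lie in [0, 1], got {lam}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


@dataclass(frozen=True)
class CandidateDecision:
    candidate_id: int
    p1: float
    p2: float
    p3: float
    p_fused: float
    label: int  # 1 = fracture kept, 0 = excluded false positive


class _DenseBlock(nn.Layer):
    def __init__(self, ndim: int, c_in: int, n_layers: int, growth: int,
                 rng: np.random.Generator, slope: float):
        self.growth = growth
        self.layers = [
            nn.Sequential(
                nn.InstanceNorm(c_in + i * growth),
                nn.LeakyReLU(slope),
                nn.Conv(ndim, c_in + i * growth, growth, 3, rng),
            )
            for i in range(n_layers)
        ]
        self.out_channels = c_in + n_layers * growth

    def parameters(self) -> list[nn.Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = x
        for layer in self.layers:
            new = layer.forward(feats)
            feats = np.concatenate([feats, new], axis=1)
        return feats

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.growth
        for layer in reversed(self.layers):
            d_new = np.ascontiguousarray(dy[:, -g:])
            dy = np.ascontiguousarray(dy[:, :-g]) + layer.backward(d_new)
        return dy


class DenseNetClassifier:
    """Maps a cubic image crop to a fracture probability in [0, 1]."""

    def __init__(self, cfg: DenseNetConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        self.cfg = cfg
        ndim = 3
        c = 2 * cfg.growth_rate
        self.stem = nn.Sequential(
            nn.Conv(ndim, in_channels, c, 3, rng),
            nn.InstanceNorm(c),
            nn.LeakyReLU(cfg.negative_slope),
            nn.MaxPool((2,) * ndim),
        )
        self.trunk: list[nn.Layer] = []
        for b, n_layers in enumerate(cfg.block_layout):
            block = _DenseBlock(ndim, c, n_layers, cfg.growth_rate, rng,
                                cfg.negative_slope)
            self.trunk.append(block)
            c = block.out_channels
            if b < len(cfg.block_layout) - 1:
                c_out = max(1, int(math.floor(c * cfg.compression)))
                self.trunk.append(nn.Sequential(
                    nn.Conv(ndim, c, c_out, 1, rng),
                    nn.AvgPool((2,) * ndim),
                ))
                c = c_out
        self.head = nn.Sequential(nn.InstanceNorm(c), nn.LeakyReLU(cfg.negative_slope))
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(c, 1, rng)
        self.out_act = nn.Sigmoid()
        self.feature_channels = c

    def parameters(self) -> list[nn.Parameter]:
        params = list(self.stem.parameters())
        for layer in self.trunk:
            params.extend(layer.parameters())
        params.extend(self.head.parameters())
        params.extend(self.fc.parameters())
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, s, s, s) -> (N,) probabilities."""
        h = self.stem.forward(x.astype(np.float32))
        for layer in self.trunk:
            h = layer.forward(h)
        h = self.head.forward(h)
        h = self.pool.forward(h)
        return self.out_act.forward(self.fc.forward(h))[:, 0]

    def backward(self, dp: np.ndarray) -> None:
        dh = self.out_act.backward(dp[:, None].astype(np.float32))
        dh = self.pool.backward(self.fc.backward(dh))
        dh = self.head.backward(dh)
        for layer in reversed(self.trunk):
            dh = layer.backward(dh)
        self.stem.backward(dh)

    def predict(self, crop: np.ndarray) -> float:
        arr = np.asarray(crop, dtype=np.float32)
        if arr.shape != (self.cfg.input_size,) * 3:
            raise ValueError(
                f"crop shape {arr.shape} does not match input_size {self.cfg.input_size}"
            )
        return float(self.forward(arr[None, None])[0])

    def predict_batch(self, crops: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(crops, dtype=np.float32)[:, None])


def build_classifier(cfg: DenseNetConfig, seed: int = 0) -> DenseNetClassifier:
    """Construct a seeded, untrained crop classifier."""
    return DenseNetClassifier(cfg, np.random.default_rng(seed))


def label_candidates(candidates: list[CandidateRegion], truth: BinaryMask
                     ) -> list[tuple[CandidateRegion, int]]:
    """Supervision for stage 2: a candidate is positive iff its voxel set
    overlaps at least one truth foreground voxel."""
    shape = truth.geometry.size
    out = []
    for cand in candidates:
        idx = cand.voxel_indices
        if idx.size and (idx.max(axis=0) >= np.asarray(shape)).any():
            raise ValueError("candidate voxels fall outside the truth geometry")
        overlap = bool(truth.values[tuple(idx.T)].any()) if idx.size else False
        out.append((cand, int(overlap)))
    return out


def _train_one(crops: np.ndarray, labels: np.ndarray, cfg: DenseNetConfig,
               train_cfg: TrainConfig, seed: int) -> DenseNetClassifier:
    """Binary cross-entropy training with class-balanced epochs: each epoch
    oversamples the minority class to parity, so a skewed candidate pool
    (many more true positives than mined negatives, or vice versa) cannot
    collapse the classifier onto the majority label."""
    clf = build_classifier(cfg, seed=seed)
    params = clf.parameters()
    opt = nn.Adam(params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    half = max(len(pos), len(neg))
    eps = 1e-7
    for _ in range(train_cfg.epochs):
        epoch_idx = np.concatenate([
            rng.choice(pos, half, replace=len(pos) < half),
            rng.choice(neg, half, replace=len(neg) < half),
        ])
        order = rng.permutation(epoch_idx)
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            x = crops[idx][:, None]
            t = labels[idx].astype(np.float64)
            p = clf.forward(x).astype(np.float64)
            pc = np.clip(p, eps, 1 - eps)
            dp = ((-t / pc + (1 - t) / (1 - pc)) / len(idx)).astype(np.float32)
            if not np.all(np.isfinite(dp)):
                raise RuntimeError("non-finite classifier gradient")
            opt.zero_grad()
            clf.backward(dp)
            if train_cfg.grad_clip > 0:
                nn.clip_grad_norm(params, train_cfg.grad_clip)
            opt.step()
    return clf


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx, int)), np.sort(np.asarray(val_idx, int))


def train_classifier_ensemble(
    labelled_crops: list[tuple[tuple[np.ndarray, np.ndarray, np.ndarray], int]],
    configs: tuple[DenseNetConfig, DenseNetConfig, DenseNetConfig],
    train_cfg: TrainConfig,
    val_fraction: float = 0.25,
) -> tuple[tuple[DenseNetClassifier, ...], FusionWeights]:
    """Train one classifier per crop size and estimate fusion weights.

    25% of the labelled candidates (stratified by label, seeded) are held
    out; each size's weight is its classifier's accuracy on that split.
    Raises :class:`DegenerateLabelsError` on a single-class training set.
    """
    if not labelled_crops:
        raise DegenerateLabelsError("no labelled candidates")
    labels = np.asarray([lab for _, lab in labelled_crops], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError(
            "training candidates are single-class; stage 2 cannot be trained"
        )
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed & 0x7FFFFFFF, 31]))
    train_idx, val_idx = _stratified_split(labels, val_fraction, rng)
    if len(val_idx) == 0:
        raise DegenerateLabelsError("validation split is empty")
    classifiers = []
    accuracies = []
    for size_i, cfg in enumerate(configs):
        crops = np.stack([c[size_i] for c, _ in labelled_crops]).astype(np.float32)
        if crops.shape[1:] != (cfg.input_size,) * 3:
            raise ValueError(
                f"size-{size_i + 1} crops have shape {crops.shape[1:]}, "
                f"config expects {(cfg.input_size,) * 3}"
            )
        clf = _train_one(crops[train_idx], labels[train_idx], cfg, train_cfg,
                         seed=train_cfg.seed + size_i)
        preds = (clf.predict_batch(crops[val_idx]) >= 0.5).astype(np.int64)
        accuracies.append(float((preds == labels[val_idx]).mean()))
        classifiers.append(clf)
    weights = FusionWeights(*accuracies)
    return tuple(classifiers), weights


def fuse_probabilities(w: FusionWeights, p1: float, p2: float, p3: float,
                       normalized: bool = True) -> float:
    """Accuracy-weighted fusion of the three per-size probabilities.

    The default normalizes by the weight sum so the result is a true
    weighted average bounded by [min(p_i), max(p_i)]; ``normalized=False``
    gives the raw weighted sum, which is not a probability unless the
    weights sum to 1.
    """
    lams = w.as_tuple()
    probs = (p1, p2, p3)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probabilities must lie in [0, 1], got {p}")
    total = sum(lams)
    if total <= 0:
        raise ValueError("fusion weights sum to zero")
    weighted = sum(l * p for l, p in zip(lams, probs))
    return float(weighted / total) if normalized else float(weighted)


def classify_candidates(
    ensemble: tuple[tuple[DenseNetClassifier, ...], FusionWeights],
    crops_per_candidate: list[MultiScaleCrops],
    threshold: float = 0.5,
) -> list[CandidateDecision]:
    """Score every candidate with all three classifiers and fuse.

    ``label`` is 1 iff the fused probability reaches ``threshold``;
    label-0 candidates are the excluded false positives.
    """
    classifiers, weights = ensemble
    if len(classifiers) != 3:
        raise ValueError("ensemble must hold exactly three classifiers")
    decisions = []
    for ms in crops_per_candidate:
        if len(ms.crops) != 3:
            raise ValueError(f"candidate {ms.candidate_ref} is missing a crop size")
        ps = [clf.predict(crop) for clf, crop in zip(classifiers, ms.crops)]
        fused = fuse_probabilities(weights, *ps)
        decisions.append(CandidateDecision(
            candidate_id=ms.candidate_ref,
            p1=ps[0], p2=ps[1], p3=ps[2],
            p_fused=fused,
            label=int(fused >= threshold),
        ))
    return decisions


def save_ensemble(ensemble: tuple[tuple[DenseNetClassifier, ...], FusionWeights],
                  directory) -> None:
    """Persist the three classifiers (npz weights + JSON config each) and
    the fusion weights."""
    classifiers, weights = ensemble
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    for i, clf in enumerate(classifiers):
        np.savez(os.path.join(directory, f"classifier_{i}.npz"),
                 **{f"p{j}": p.value for j, p in enumerate(clf.parameters())})
        with open(os.path.join(directory, f"classifier_{i}.json"), "w") as fh:
            json.dump(asdict(clf.cfg), fh, indent=2)
    with open(os.path.join(directory, "fusion_weights.json"), "w") as fh:
        json.dump(asdict(weights), fh, indent=2)


def load_ensemble(directory) -> tuple[tuple[DenseNetClassifier, ...], FusionWeights]:
    directory = os.fspath(directory)
    classifiers = []
    for i in range(3):
        with open(os.path.join(directory, f"classifier_{i}.json")) as fh:
            meta = json.load(fh)
        meta["block_layout"] = tuple(meta["block_layout"])
        clf = build_classifier(DenseNetConfig(**meta))
        data = np.load(os.path.join(directory, f"classifier_{i}.npz"))
        for j, p in enumerate(clf.parameters()):
            p.value[...] = data[f"p{j}"]
        classifiers.append(clf)
    with open(os.path.join(directory, "fusion_weights.json")) as fh:
        weights = FusionWeights(**json.load(fh))
    return tuple(classifiers), weights
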