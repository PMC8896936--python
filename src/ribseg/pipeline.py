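"""End-to-end orchestration of the two-stage recognition experiment.

``run_two_stage_experiment`` is the in-memory core: it generates a phantom
cohort, fingerprints and preprocesses it, trains the stage-1 segmenter,
mines stage-2 training candidates, trains the classifier ensemble, and
evaluates both stages on held-out phantoms.  ``run_pipeline`` wraps the
same stages with on-disk artifacts and a run manifest for the CLI.

Every stage draws its randomness from a seed derived by hashing the global
seed with the stage name, so adding a stage never perturbs the draws of an
earlier one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .classifier import (
    DenseNetConfig,
    classify_candidates,
    label_candidates,
    train_classifier_ensemble,
)
from .geometry import BinaryMask, ImageVolume
from .inference import (
    CandidateRegion,
    crop_multiscale,
    extract_candidates,
    predict_volume_padded,
)
from .losses import LossConfig, LossValues
from .metrics import DetectionReport, detection_report, dice_metric
from .phantom import PhantomConfig, PhantomSample, generate_dataset, write_sample
from .preprocess import DatasetFingerprint, compute_fingerprint, preprocess_sample
from .seg_model import (
    PRESETS,
    CascadeConfig,
    CascadeSegmenter,
    TrainConfig,
    train_cascade,
    train_segmenter,
)


def _fused_probability(segmenter, image: ImageVolume, overlap: float):
    """Dispatch whole-volume prediction over plain and cascade segmenters."""
    if isinstance(segmenter, CascadeSegmenter):
        return segmenter.predict_full(image, overlap)
    return predict_volume_padded(segmenter, image, overlap=overlap)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class PipelineConfig:
    """Full-default desk-scale profile: 20 phantoms of 64^3 voxels with 3
    lesions and 3 off-rib decoys each, a tiny 3-D segmenter, and a
    three-size classifier ensemble on 16/24/32-voxel crops."""

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        grid_size=(64, 64, 64), spacing_mm=(1.25, 0.75, 0.75),
        n_ribs=3, n_lesions=3, n_decoys=3, uncertain_fraction=0.1,
    ))
    n_train: int = 14
    n_test: int = 6
    unet_preset: str = "tiny_3d"
    cascade: bool = False
    cascade_cfg: CascadeConfig = field(default_factory=CascadeConfig)
    seg_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        batch_size=2, epochs=40, learning_rate=1e-2, fg_patch_fraction=0.7,
        steps_per_epoch=12,
    ))
    cls_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        batch_size=8, epochs=12, learning_rate=2e-3,
    ))
    loss: LossConfig = field(default_factory=LossConfig)
    threshold: float = 0.5
    overlap: float = 0.5
    connectivity: int = 26
    min_component_size: int = 1
    crop_sizes: tuple[int, int, int] = (16, 24, 32)
    growth_rate: int = 8
    block_layout: tuple[int, ...] = (2, 2)
    compression: float = 0.5
    decision_threshold: float = 0.5
    mining: str = "mined"  # or "gt_plus_random"
    target_spacing_override: tuple[float, float, float] | None = None
    seed: int = 0

    def classifier_configs(self) -> tuple[DenseNetConfig, ...]:
        return tuple(
            DenseNetConfig(input_size=s, growth_rate=self.growth_rate,
                           block_layout=self.block_layout,
                           compression=self.compression)
            for s in self.crop_sizes
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class VolumeEvaluation:
    stage1: DetectionReport
    stage2: DetectionReport
    dice: float
    n_candidates: int
    n_accepted: int


@dataclass
class ExperimentResult:
    """Aggregate outcome of one seeded two-stage experiment."""

    loss_history: list[LossValues]
    fusion_weights: tuple[float, float, float]
    per_volume: list[VolumeEvaluation]
    n_truth: int
    n_detected_stage1: int
    n_detected_stage2: int
    n_fp_stage1: int
    n_fp_stage2: int
    n_predictions_stage1: int
    n_predictions_stage2: int

    @property
    def recognition_rate_stage1(self) -> float:
        return self.n_detected_stage1 / self.n_truth if self.n_truth else 1.0

    @property
    def recognition_rate(self) -> float:
        """Held-out per-lesion recognition rate after both stages."""
        return self.n_detected_stage2 / self.n_truth if self.n_truth else 1.0

    @property
    def fp_rate_stage1(self) -> float:
        return (self.n_fp_stage1 / self.n_predictions_stage1
                if self.n_predictions_stage1 else 0.0)

    @property
    def fp_rate(self) -> float:
        return (self.n_fp_stage2 / self.n_predictions_stage2
                if self.n_predictions_stage2 else 0.0)

    @property
    def true_detection_retention(self) -> float:
        """Fraction of stage-1 detected lesions still detected after stage 2."""
        return (self.n_detected_stage2 / self.n_detected_stage1
                if self.n_detected_stage1 else 1.0)

    @property
    def mean_dice(self) -> float:
        return float(np.mean([v.dice for v in self.per_volume]))


def _preprocess_cohort(samples: list[PhantomSample],
                       fingerprint: DatasetFingerprint
                       ) -> list[tuple[ImageVolume, BinaryMask]]:
    out = []
    for s in samples:
        img, mask, _ = preprocess_sample(s.image, s.labels, fingerprint)
        out.append((img, mask))
    return out


def _random_background_centres(mask: np.ndarray, n: int, margin: int,
                               rng: np.random.Generator) -> list[tuple[int, ...]]:
    centres = []
    shape = mask.shape
    fg = np.argwhere(mask > 0)
    for _ in range(n * 20):
        if len(centres) >= n:
            break
        c = tuple(int(rng.integers(0, s)) for s in shape)
        if mask[c]:
            continue
        if len(fg) and np.min(np.abs(fg - np.asarray(c)).sum(axis=1)) < margin:
            continue
        centres.append(c)
    return centres


def _mine_training_candidates(cfg: PipelineConfig, segmenter,
                              train_pre: list[tuple[ImageVolume, BinaryMask]],
                              rng: np.random.Generator):
    """Stage-2 supervision: (three crops, label) pairs from training volumes."""
    labelled = []
    for img, mask in train_pre:
        if cfg.mining == "mined":
            prob = _fused_probability(segmenter, img, cfg.overlap)
            cands = extract_candidates(prob, cfg.threshold, cfg.connectivity,
                                       cfg.min_component_size)
            for cand, lab in label_candidates(cands, mask):
                ms = crop_multiscale(img, cand, cfg.crop_sizes)
                labelled.append((ms.crops, lab))
        elif cfg.mining == "gt_plus_random":
            from scipy import ndimage
            comp, n = ndimage.label(mask.values,
                                    structure=ndimage.generate_binary_structure(3, 3))
            pos_centres = [tuple(np.argwhere(comp == i).mean(axis=0))
                           for i in range(1, n + 1)]
            neg_centres = _random_background_centres(
                mask.values, max(1, n), margin=max(cfg.crop_sizes) // 2, rng=rng)
            for lab, centres in ((1, pos_centres), (0, neg_centres)):
                for j, c in enumerate(centres):
                    v = np.floor(c).astype(int)
                    fake = CandidateRegion(
                        component_id=j + 1, voxel_count=1,
                        bbox=tuple((int(a), int(a)) for a in v),
                        centroid_voxel=tuple(float(a) for a in v),
                        mean_probability=1.0,
                        voxel_indices=v[None, :],
                    )
                    ms = crop_multiscale(img, fake, cfg.crop_sizes)
                    labelled.append((ms.crops, lab))
        else:
            raise ValueError(f"unknown mining mode {cfg.mining!r}")
    if cfg.mining == "mined" and labelled:
        # mined negatives track the segmenter's false positives, which can
        # be scarce when stage 1 is accurate; always blend in one random
        # background negative per training volume so the negative class
        # spans both hard (mined) and easy (random) examples
        for img, mask in train_pre:
            for c in _random_background_centres(
                    mask.values, 1, margin=max(cfg.crop_sizes) // 2, rng=rng):
                fake = CandidateRegion(
                    component_id=0, voxel_count=1,
                    bbox=tuple((int(v), int(v)) for v in np.floor(c)),
                    centroid_voxel=tuple(float(v) for v in c),
                    mean_probability=1.0,
                    voxel_indices=np.asarray([np.floor(c)], dtype=int),
                )
                labelled.append((crop_multiscale(img, fake, cfg.crop_sizes).crops, 0))
    return labelled


def run_two_stage_experiment(cfg: PipelineConfig) -> ExperimentResult:
    """Run the full experiment in memory and aggregate held-out results."""
    phantom_cfg = dataclasses.replace(
        cfg.phantom, seed=stage_seed(cfg.seed, "simulate"))
    samples = generate_dataset(phantom_cfg, cfg.n_train + cfg.n_test)
    train_samples = samples[:cfg.n_train]
    test_samples = samples[cfg.n_train:]

    fingerprint = compute_fingerprint(
        [(s.image, s.labels) for s in train_samples])
    if cfg.target_spacing_override is not None:
        fingerprint = dataclasses.replace(
            fingerprint, target_spacing_mm=tuple(cfg.target_spacing_override))
    train_pre = _preprocess_cohort(train_samples, fingerprint)
    test_pre = _preprocess_cohort(test_samples, fingerprint)

    seg_cfg = PRESETS[cfg.unet_preset]
    seg_train = dataclasses.replace(
        cfg.seg_train, seed=stage_seed(cfg.seed, "train-seg"))
    if cfg.cascade:
        coarse, fine, history = train_cascade(
            train_pre, cfg.cascade_cfg, seg_train, cfg.loss, return_history=True)
        segmenter = CascadeSegmenter(coarse, fine, cfg.cascade_cfg.coarse_spacing_mm)
    else:
        segmenter, history = train_segmenter(train_pre, seg_cfg, seg_train, cfg.loss)

    mine_rng = np.random.default_rng(stage_seed(cfg.seed, "mine"))
    labelled = _mine_training_candidates(cfg, segmenter, train_pre, mine_rng)
    # safety valve: if the segmenter surfaces nothing at all on its own
    # training volumes, continue training (bounded, seeded) and re-mine
    extensions = 0
    while not labelled and not cfg.cascade and extensions < 2:
        extra = dataclasses.replace(
            seg_train, epochs=12,
            seed=stage_seed(cfg.seed, f"train-seg-ext{extensions}"))
        segmenter, more = train_segmenter(train_pre, seg_cfg, extra, cfg.loss,
                                          net=segmenter)
        history = history + more
        labelled = _mine_training_candidates(cfg, segmenter, train_pre, mine_rng)
        extensions += 1
    cls_train = dataclasses.replace(
        cfg.cls_train, seed=stage_seed(cfg.seed, "train-cls"))
    ensemble = train_classifier_ensemble(
        labelled, cfg.classifier_configs(), cls_train)

    per_volume: list[VolumeEvaluation] = []
    for img, mask in test_pre:
        prob = _fused_probability(segmenter, img, cfg.overlap)
        cands = extract_candidates(prob, cfg.threshold, cfg.connectivity,
                                   cfg.min_component_size)
        crops = [crop_multiscale(img, c, cfg.crop_sizes) for c in cands]
        decisions = classify_candidates(ensemble, crops, cfg.decision_threshold)
        kept_ids = {d.candidate_id for d in decisions if d.label == 1}
        accepted = [c for c in cands if c.component_id in kept_ids]
        stage1 = detection_report(cands, mask)
        stage2 = detection_report(accepted, mask)
        pred_mask = BinaryMask(values=(prob.values >= cfg.threshold).astype(np.uint8),
                               geometry=img.geometry)
        per_volume.append(VolumeEvaluation(
            stage1=stage1, stage2=stage2,
            dice=dice_metric(pred_mask, mask),
            n_candidates=len(cands), n_accepted=len(accepted),
        ))

    return ExperimentResult(
        loss_history=history,
        fusion_weights=ensemble[1].as_tuple(),
        per_volume=per_volume,
        n_truth=sum(v.stage1.n_truth_instances for v in per_volume),
        n_detected_stage1=sum(v.stage1.n_detected for v in per_volume),
        n_detected_stage2=sum(v.stage2.n_detected for v in per_volume),
        n_fp_stage1=sum(v.stage1.n_false_positive_predictions for v in per_volume),
        n_fp_stage2=sum(v.stage2.n_false_positive_predictions for v in per_volume),
        n_predictions_stage1=sum(v.stage1.n_predictions for v in per_volume),
        n_predictions_stage2=sum(v.stage2.n_predictions for v in per_volume),
    )


def run_pipeline(cfg: PipelineConfig, workdir) -> dict:
    """Run the experiment and persist artifacts plus a run manifest.

    The manifest records the config hash, per-stage seeds and wall time,
    artifact paths and the final detection report; any stage failure is
    recorded with the stage name and re-raised.
    """
    workdir = os.fspath(workdir)
    os.makedirs(workdir, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("simulate", "train-seg", "mine", "train-cls")},
        "stages": {},
        "artifacts": {},
    }

    def _record(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}

    stage = "simulate"
    try:
        t0 = time.time()
        phantom_cfg = dataclasses.replace(
            cfg.phantom, seed=stage_seed(cfg.seed, "simulate"))
        samples = generate_dataset(phantom_cfg, cfg.n_train + cfg.n_test)
        sim_dir = os.path.join(workdir, "phantoms")
        os.makedirs(sim_dir, exist_ok=True)
        for s in samples:
            write_sample(
                s,
                os.path.join(sim_dir, f"{s.index:03d}_image.nii.gz"),
                os.path.join(sim_dir, f"{s.index:03d}_label.nii.gz"),
                os.path.join(sim_dir, f"{s.index:03d}_catalogue.json"),
            )
        manifest["artifacts"]["phantoms"] = sim_dir
        _record(stage, t0)

        stage = "experiment"
        t0 = time.time()
        result = run_two_stage_experiment(cfg)
        _record(stage, t0)

        stage = "evaluate"
        t0 = time.time()
        manifest["results"] = {
            "recognition_rate_stage1": result.recognition_rate_stage1,
            "recognition_rate": result.recognition_rate,
            "fp_rate_stage1": result.fp_rate_stage1,
            "fp_rate": result.fp_rate,
            "n_truth_instances": result.n_truth,
            "n_fp_stage1": result.n_fp_stage1,
            "n_fp_stage2": result.n_fp_stage2,
            "true_detection_retention": result.true_detection_retention,
            "mean_dice": result.mean_dice,
            "fusion_weights": list(result.fusion_weights),
            "loss_first_epoch": result.loss_history[0].total if result.loss_history else None,
            "loss_last_epoch": result.loss_history[-1].total if result.loss_history else None,
        }
        loss_csv = os.path.join(workdir, "training_loss.csv")
        with open(loss_csv, "w") as fh:
            fh.write("epoch,l_dice,l_ce,l_contour,total\n")
            for i, v in enumerate(result.loss_history):
                fh.write(f"{i},{v.l_dice:.6f},{v.l_ce:.6f},{v.l_contour:.6f},{v.total:.6f}\n")
        manifest["artifacts"]["training_loss"] = loss_csv
        _record(stage, t0)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(os.path.join(workdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(os.path.join(workdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
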