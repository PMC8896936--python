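"""Run the whole two-stage experiment at miniature scale.

Simulate -> preprocess -> train segmenter -> sliding-window predict ->
extract candidates -> train the three-size classifier ensemble -> classify
-> evaluate.  The default desk-scale profile (20 phantoms of 64^3) takes
several minutes; this miniature profile finishes in about a minute.
"""

from ribseg import PhantomConfig, PipelineConfig, TrainConfig, run_two_stage_experiment

cfg = PipelineConfig(
    phantom=PhantomConfig(grid_size=(32, 32, 32), spacing_mm=(1, 1, 1),
                          n_ribs=2, n_lesions=2, n_decoys=1, noise_sd=10.0),
    n_train=5, n_test=2,
    seg_train=TrainConfig(batch_size=2, epochs=16, steps_per_epoch=8,
                          learning_rate=2e-2, fg_patch_fraction=0.8),
    cls_train=TrainConfig(batch_size=4, epochs=6, learning_rate=2e-3),
    crop_sizes=(8, 12, 16),
    mining="gt_plus_random",
    seed=0,
)
res = run_two_stage_experiment(cfg)

print(f"held-out lesions:          {res.n_truth}")
print(f"stage-1 recognition rate:  {res.recognition_rate_stage1:.2f}")
print(f"stage-1 false positives:   {res.n_fp_stage1} "
      f"(rate {res.fp_rate_stage1:.2f})")
print(f"stage-2 recognition rate:  {res.recognition_rate:.2f}")
print(f"stage-2 false positives:   {res.n_fp_stage2} (rate {res.fp_rate:.2f})")
print(f"fusion weights (per-size validation accuracy): "
      f"{tuple(round(w, 2) for w in res.fusion_weights)}")
print(f"mean held-out Dice:        {res.mean_dice:.3f}")
# Stage 2 can only remove candidates: its prediction set is always a subset
# of stage 1's, so the false-positive count can only go down.
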