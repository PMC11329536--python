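# annoret

A desk-scale pipeline for studying how annotator variability and
annotation-integration strategies change the performance of retrained
lesion-detection CAD software. It covers two synthetic tasks — nodule-like
lesions in chest-style volumes and aneurysm-like bumps on vessel trees in
brain-style volumes — and runs end to end on a single CPU:

1. **`annoret.core`** — domain types (volumes, spherical ROIs, annotation
   sets, candidates, dataset manifests), NIfTI-1 volume I/O, a JSON/CSV
   annotation dialect, and world↔voxel coordinate transforms (world mm,
   0-based indices, half-open VOI bounds).
2. **`annoret.synth`** — phantom generation with placed ground-truth
   lesions and confusable distractor structures, dataset assembly with the
   default subset design (initial 50/0, two retraining subsets 40/35 each,
   test 50/50, with 10 distractor-bearing "ambiguous" negatives per
   retraining/test subset), and simulated annotators with tunable
   diameter-dependent sensitivity, false-annotation rate, centroid/size
   jitter, distractor confusion, and a CAD-assisted second reading pass.
3. **`annoret.detector`** — two-stage CAD analog: isotropic resampling
   (plus piecewise-linear intensity standardization for the brain task),
   organ/vessel mask extraction, multiscale LoG blob candidates, and a VOI
   classifier trained with 29-fold positive augmentation and per-epoch
   negative undersampling to a 1:1 class ratio. Classifiers (`cnn3d`,
   `cnn_mip`, `linear_baseline`) run on a small deterministic numpy
   neural-net core (no GPU or deep-learning framework required).
4. **`annoret.integration`** — cross-annotator ROI matching at a 3 mm
   centroid threshold (greedy one-to-one per annotator pair, connected
   components, chain flagging) and AND / OR / VOTING integration with
   centroid/diameter averaging.
5. **`annoret.evaluation`** — lesion-level hit scoring, FROC curves, CPM
   (mean sensitivity at 1/8…8 FPs/case), and the Steel–Dwass all-pairs
   rank test with an exact permutation fallback.
6. **`annoret.study`** — the full two-round retraining protocol (initial
   model → per-annotator retrained models → CAD-referenced second round),
   integration experiments per strategy × cohort, and summary tables.

## CLI

```bash
annoret generate --task chest --seed 1 --out data/            # phantom dataset
annoret annotate --manifest data/manifest.json --out ann.json # simulated cohort
annoret integrate --annotations ann.json --strategy voting --threshold-mm 3 --out integrated/
annoret evaluate --manifest data/manifest.json --candidates cands.csv --out froc.json
annoret compare --groups cpms.csv --out steel_dwass.json
annoret study --task chest --seed 7 --out results/            # full protocol
```

`annoret study` accepts a YAML config (`--config`) overriding subset
counts, detector hyperparameters and phantom parameters.

## Notes on scale

Defaults are desk-scale: 64³ isotropic phantoms, 16³ VOIs, the
`linear_baseline` classifier and ≤ 20 epochs. The published-scale settings
(32³ VOIs, 3D residual / MIP conv-nets, 500 epochs, 0.469 mm brain
resampling) remain available through `DetectorConfig.for_task(task,
desk=False)` but are not practical on one CPU.
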