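# pixphen

Pixel-level and cell-level phenotyping of highly multiplexed tissue images.

`pixphen` reimplements a pixel-clustering phenotyping pipeline: per-marker
grayscale images are smoothed, retained pixels are normalized (per-pixel
sum-to-1, then per-marker 99.9th-percentile division), overclustered with a
self-organizing map (typically 100 clusters), collapsed into annotated
phenotypes by consensus hierarchical metaclustering of capped z-scored
cluster profiles, and rendered back into pixel phenotype maps. Cells are then
phenotyped from the composition of pixel clusters inside their segmentation
masks — more robust to boundary spillover and batch effects than the
classical integrated-expression baseline, which is also provided for
comparison. A cluster consistency score quantifies reproducibility across
seeded replicate runs.

A first-class synthetic-data module simulates multi-channel images of
elliptical cells with known phenotype signatures, Poisson noise, dropout,
per-FOV gain drift, and boundary spillover, with matched ground-truth label
maps — so every stage is testable without external data.

## CLI

All commands read a YAML config (`run.yaml`) with per-stage sections; every
source of randomness is an explicit seed, and each run writes a
`manifest.json` with config, seeds, input digests, and output inventory.

```sh
# generate a demo dataset (with ground truth) plus a ready run.yaml
pixphen simulate --out demo/ --seed 1

# full pixel clustering: preprocessing -> SOM -> consensus -> phenotype maps
pixphen pixel-cluster --config demo/run.yaml

# cell phenotyping from pixel-cluster composition (or the baseline)
pixphen cell-cluster --config demo/run.yaml --features composition
pixphen cell-cluster --config demo/run.yaml --features integrated

# reproducibility: replicate runs + cluster consistency score
pixphen consistency --config demo/run.yaml --replicates 5 --coverage 0.95

# score predicted labels against a reference (ARI, per-class F1)
pixphen evaluate --pred pred.csv --truth truth.csv --out metrics/

# render a label-map TIFF as a color PNG
pixphen render --map demo/out/maps/fov0_phenotype_map.tiff --out map.png
```

Dataset layout: `dataset_root/<fov_id>/<marker>.tiff`, with the segmentation
mask at `dataset_root/<fov_id>/segmentation.tiff`. Metacluster annotations
are edited by hand in the remap CSV (`som_cluster,metacluster,annotation`)
emitted under `out/profiles/remap.csv` and passed back via the `remap`
config key.

## Package layout

| module            | role                                                        |
|-------------------|-------------------------------------------------------------|
| `synthetic`       | ground-truth simulator (signatures, FOVs, datasets)          |
| `image_io`        | TIFF/CSV/JSON readers and writers, remap-table validation    |
| `preprocessing`   | blur, pixel extraction/exclusion, normalization cascade      |
| `som`             | online SOM training and assignment                           |
| `metaclustering`  | cluster profiles, capped z-scores, consensus metaclustering  |
| `pixel_pipeline`  | end-to-end pixel clustering, phenotype maps, compositions    |
| `cell_pipeline`   | composition & integrated-expression cell clustering          |
| `consistency`     | replicate orchestration, cluster consistency score           |
| `evaluation`      | ARI, silhouette, F1, Otsu positivity baseline, Spearman      |
| `cli`             | `pixphen` entry point, YAML config, run manifests            |

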