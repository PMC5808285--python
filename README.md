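# hsiduct

Semi-automated detection of ductal carcinoma in situ (DCIS) in
hyperspectral microscope images of histology slides, driven end to end by
a synthetic hyperspectral phantom generator.

The pipeline mirrors a snapshot-HSI histopathology workflow:

1. **Phantom cohorts** (`hsiduct.phantom`) — labeled synthetic patients,
   each with {normal, dcis} x {H&E-stained, unstained} reflectance cubes
   (443 x 313 pixels, 31 bands over 461–641 nm by default), class-specific
   endmember spectra whose stained separation peaks at the band nearest
   550 nm, per-patient gain/tilt variation, pixel noise, duct-ring texture
   and irregular carcinoma blobs with ground-truth masks.
2. **Cube I/O** (`hsiduct.hypercube`) — ENVI header/raw pairs (BSQ, BIL,
   BIP, both byte orders), PGM masks, pixel/band accessors, mask-aware
   flattening to pixel-by-band matrices.
3. **ROI spectral analysis** (`hsiduct.spectra`) — four random square
   regions per slide, ten subsample measurements per region, mean ± SD
   summaries, per-band standardized class separation and best-band
   selection.
4. **K-means** (`hsiduct.kmeans`) — written from first principles:
   Euclidean assignment, within-cluster sum-of-squares objective,
   mean-update, random or farthest-apart initialization, stopping when no
   pixel is reassigned.
5. **Detection pipeline** (`hsiduct.pipeline`) — leave-one-patient-out
   training on pooled ROI spectra, majority-vote cluster→label mapping,
   held-out classification, confusion-matrix metrics (sensitivity,
   specificity, TNR, FPR) and red/blue detection overlays.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), brute-force and
exhaustive-partition oracles for the clustering core, a cross-check
against scikit-learn's K-means, and `tests/test_acceptance.py` with one
test per acceptance criterion (the full-scale cohort tests take ~30 s).

## CLI

One executable, one subcommand per stage; all randomness flows from
`--seed`:

```sh
hsiduct simulate --seed 42 --out cohort/            # synthetic cohort
hsiduct spectra --cohort cohort/ --seed 42 --out separation.tsv
hsiduct select-band --cohort cohort/ --seed 42      # prints e.g. 551
hsiduct train --cohort cohort/ --seed 42 --out model.json
hsiduct classify --model model.json --cube cohort/patient_10/dcis_stained.hdr \
    --out pred.pgm --overlay overlay.png
hsiduct evaluate --pred pred.pgm --truth cohort/patient_10/dcis_stained.pgm
hsiduct run-all --seed 42 --out results/            # everything, end to end
```

`run-all` writes `report.json`, `metrics.tsv`, `per_patient_accuracy.tsv`,
`centroids.tsv`, `separation.tsv` and overlay PNGs. A plain-text
`key=value` config file (see `hsiduct.pipeline.RunConfig`) can be passed
with `--config`; flags override it.

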