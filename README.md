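# elene

An interpretable radiomics pipeline for classifying lymph nodes on
contrast-enhanced CT as **normal**, **metastatic**, or **extranodal
extension (ENE)**:

1. **Preprocessing** (`elene.io_preprocess`) — window/rescale CT slices to
   [0, 255], rasterize contour polygons, refine masks
   (dilate/fill/erode), and derive the geometric primitives every
   extractor uses: the largest mask section, its largest inscribed square,
   inner/outer boundary bands at disc radii 3/5/10 px, and an isotropic 3D
   model with a watertight triangulated surface.
2. **Feature extraction** (`elene.feature_catalog`,
   `elene.texture_features`, `elene.morphology_features`) — a frozen
   catalog of 460 features in 26 subsets across 6 types: 18 GLCM
   statistics x 20 (direction, distance) configurations at 16 gray
   levels, 11 GLSZM statistics, 11 first-order gray-level statistics, 29
   3D + 24 2D shape features, 6 boundary features per band radius, and
   the 7 Hu invariant moments.
3. **Coarse selection** (`elene.coarse_selection`) — rank all 26 subsets
   by stratified-CV SVM accuracy on three tasks (metastatic vs normal,
   ENE vs rest, three-class) and pool the top five per task.
4. **Fine selection** (`elene.ibcga_optimizer`) — an inheritable
   combinatorial GA that selects exactly `r` features per phase
   (`r_start` down to `r_end`), co-optimizes the SVM cost C and RBF gamma
   on log2 grids, and uses orthogonal-array crossover (L8/L16) with
   bit-swap mutation; fitness is stratified-CV accuracy.
5. **Ensemble** (`elene.ensemble_classifier`) — 31 independently seeded
   optimizer runs, each retrained on the full training set; plurality
   voting with vote-fraction scores for the binary ENE/metastasis views.
6. **Evaluation** (`elene.evaluation`) — confusion-matrix rates (percent)
   and tie-corrected Mann–Whitney ROC/AUC.

A synthetic phantom generator (`elene.synthetic_data`) produces
class-conditional lymph-node volumes (texture variance ordered
normal > metastatic > ENE, ENE-widest boundary blur, configurable
solidity direction) and planted-signal feature tables, so the full
pipeline is testable offline.

## CLI

```sh
elene simulate --classes 100 100 100 --seed 0 --out cohort/
elene extract --bundles cohort/train --out train.csv
elene coarse-select --table train.csv --out rank.json --seed 0
elene train --table train.csv --pool rank.json --out model.json --seed 0
elene predict --model model.json --table test.csv --out pred.csv
elene evaluate --pred binary.csv --out metrics.json
```

`elene preprocess` converts a DICOM series + RT Structure Set (or a NIfTI
volume/mask fixture pair) into per-node bundles. Every command writes a
`.prov.json` provenance sidecar.

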