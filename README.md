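# lungcad

Lung CT nodule / ground-glass-opacity (GGO) candidate detection toolkit:

- **Parenchyma segmentation** — threshold binarization, removal of
  border-connected external air, per-slice hole filling (airways), contour
  corrosion (erosion) and mending/expansion (opening + per-component
  closing), then masking so only lung parenchyma remains.
- **Candidate detection** — per-slice thresholding inside the lung mask,
  deletion of small and of thin/elongated (vessel-like) structures by
  moment-ellipse analysis, and extraction of 64×64 tri-slice ROI stacks
  around each surviving component's centroid.
- **Tri-slice RGB encoding** — the three consecutive slices of an ROI are
  windowed to bytes and superimposed on the red, green and blue channels.
  Spherical structures produce channel-coincident pseudo-color blobs;
  obliquely tilted vessels shift between channels. A deterministic
  `baseline` scorer (channel-coincidence × blob compactness) quantifies
  this and stands in for a trained CNN; trained models can be plugged in
  through the scorer registry.
- **Detection evaluation** — confusion tallies, sensitivity/TPR, precision,
  specificity, false-positive rate, F-score and accuracy (with explicit
  "undefined" handling), threshold sweeps, greedy detection-to-truth
  matching, 3-D detection merging, size-stratified sensitivity reports and
  average false positives per patient.
- **Synthetic CT phantoms** — air background, soft-tissue body, two lung
  ellipsoids, straight cylindrical vessels at controlled tilt angles, and
  solid / GGO / juxtapleural spherical nodules, with exact ground truth
  (annotations + lung mask) and seeded reproducibility. Every stage above
  is tested against these phantoms; no external data is needed.

I/O: NIfTI and TIFF raster stacks (read/write), DICOM series (read;
requires the optional `pydicom` extra), LIDC-style reading-session XML
annotations with the nine characteristic ratings, PNG export of
pseudo-color composites, CSV reports.

## CLI

```sh
lungcad phantom --difficulty easy --seed 1 --noise-sd 20 --out vol.nii \
    --annotations-out truth.csv --mask-out gt_mask.nii
lungcad segment vol.nii --mask-out mask.nii --parenchyma-out parenchyma.nii
lungcad detect vol.nii --mask mask.nii --out candidates.csv
lungcad encode vol.nii --center 28 56 38 --out roi.png
lungcad score vol.nii --center 28 56 38 --scorer baseline
lungcad evaluate scores.csv            # score,truth CSV -> Markdown sweep
lungcad run --source phantom:easy --seed 1 --out-dir out/
```

`lungcad run` executes the full pipeline (segment → detect → encode →
score → evaluate) and writes a deterministic JSON report plus the resolved
config; re-running the emitted config reproduces the report byte for byte.

## Layout

```
src/lungcad/
  io.py            volumes (NIfTI/TIFF/DICOM), annotations (XML/CSV), PNG
  phantom.py       synthetic phantom generator + documented presets
  segmentation.py  parenchyma extraction pipeline
  candidates.py    component labeling, filters, ROI extraction
  encoding.py      windowing, RGB superposition, scorers
  evaluation.py    metrics, matching, sweeps, size-stratified reports
  pipeline.py      end-to-end orchestration
  cli.py           click command-line interface
tests/             pytest suite; test_acceptance.py maps the acceptance
                   criteria one test (group) per criterion
```
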