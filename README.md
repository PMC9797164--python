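# mmdir

Multi-metric deformable image registration for aligning pre-operative and
post-operative CT-like volumes, aimed at tumor-bed contour propagation in
breast radiotherapy planning. Three cost terms are combined in one weighted
objective minimized over a multi-resolution cubic B-spline free-form
deformation:

* **fiducial** — mean Euclidean distance (mm) between paired landmarks,
* **region** — Kappa-statistic overlap (`2|A∩B| / (|A|+|B|)`) of paired ROI
  masks, sampled softly through the transform,
* **intensity** — Parzen-window mutual information of intensity samples.

Default weights are (1, 1, 100). Zeroing weights reproduces the classic
method family: intensity-only (`i`), region+intensity (`ri`),
fiducial+intensity (`fi`) and all three (`fri`).

The package also provides:

* automatic feature extraction (3D Harris corners, NCC point matching, Otsu
  threshold segmentation),
* evaluation (grouped target registration error, Dice, Hausdorff,
  checkerboard and orange/cyan overlay renderings),
* contour operations (mask propagation through a transform, physical-mm
  margin expansion, skin-depth limiting),
* a synthetic resection phantom: paired pre/post-operative volumes with a
  known smooth deformation, grouped landmarks, gland ROIs and a seroma-like
  cavity with marker clips, so the whole pipeline is testable without
  patient data.

## Command line

```bash
# generate a phantom case directory (volumes, masks, point files, manifest)
mmdir phantom --out-dir case0 --seed 0

# register (multi-metric; omit points/ROIs for intensity-only)
mmdir register --fixed case0/fixed.mha --moving case0/moving.mha \
    --fixed-points case0/fiducials_fixed.txt --moving-points case0/fiducials_moving.txt \
    --fixed-roi case0/gland_fixed.mha --moving-roi case0/gland_moving.mha \
    --out-transform t.json --out-resampled moved.mha --seed 1

# propagate a contour and evaluate
mmdir propagate --mask case0/tumor_moving.mha --transform t.json \
    --like case0/fixed.mha --out propagated.mha
mmdir evaluate --transform t.json \
    --fixed-points case0/landmarks_fixed.txt --moving-points case0/landmarks_moving.txt \
    --mask-a propagated.mha --mask-b case0/tumor_bed.mha --report report.json

# margin operations (tumor+2cm limited to the skin surface)
mmdir expand --mask case0/tumor_moving.mha --margin-mm 20 \
    --limit case0/body_moving.mha --out tumor2.mha

# feature extraction
mmdir features corners --image case0/moving.mha --mask case0/gland_moving.mha \
    --n-points 30 --out corners.txt

# replay the four-method comparison on a case
mmdir compare --case-dir case0 --methods i,ri,fi,fri --out comparison.csv --seed 2
```

Configuration is YAML (`--config`), with `registration:` and `phantom:`
sections mirroring `RegistrationConfig` and `PhantomConfig`; unknown keys
are rejected. Volumes are MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz);
point files are plain text (`point` / count / one `x y z` per line, world
mm); transforms are self-describing JSON.

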