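# discmri

Quantitative lumbar intervertebral-disc MRI analysis driven by a synthetic
spine-phantom generator. The package simulates a four-group activity cohort
(per-disc degeneration grades, known T2 / proton-density / water-fraction
ground truth), renders sagittal label volumes, and simulates three
acquisitions — 8-echo spin-echo, single-echo T2w, and dual-echo complex
Dixon with a smooth off-resonance field and Rician/complex-Gaussian noise.
The analysis side reconstructs:

* **T2 maps** — voxelwise ordinary least squares on log-intensity
  (`discmri.relaxometry`),
* **water-percentage maps** — two-point asymmetric-echo water/fat separation
  with field-map candidate enumeration, region growing, and Gauss–Newton
  refinement (`discmri.dixon`),
* **disc metrics** — five anteroposterior subregions per ROI slice, central
  three-slice pooling, whole-disc / nucleus / nucleus-annulus-ratio means
  (`discmri.roi`),
* **cohort statistics** — per-disc measurement table, unpaired t-tests of
  activity groups vs the sedentary referent and grades 2–4 vs grade 1,
  Pearson correlation grid, summary tables (`discmri.cohort_stats`),
* **disc surfaces** — piecewise-linear interpolated subregion grids
  (`discmri.surfaces`).

## CLI

```bash
discmri all --out run/ --seed 1                # full synthetic pipeline
discmri all --config config.yaml --out run/    # custom cohort / noise / stats
discmri simulate --out sim/ --seed 1           # volumes (NIfTI), ROIs (JSON), truth (CSV)
discmri t2map --input sim/volumes/S001_multiecho.nii --out S001
discmri dixon --prefix sim/volumes/S001_dixon --out S001
discmri measure --map S001_t2.nii --rois sim/volumes/S001_rois.json --out metrics.csv
discmri report --table run/disc_table.csv --out report/
```

Stage artifacts live on disk between steps, so real multi-echo / dual-echo
NIfTI volumes plus polygon-ROI JSON files can enter at any stage. A config
YAML mirrors the `RunConfig` fields (cohort layout, noise sigmas, solver
options, stats options); every CSV output carries a `# discmri <version>
seed=<seed>` provenance header and `provenance.json` echoes the full config.

## Conventions

Volumes use 0-based (slice, row, column) indexing; anterior is the lower
column index. ROI JSON: `{disc_id, slices: [{index, vertices: [[row, col],
...]}]}` with the anterior-most vertex first. The nucleus is operationalized
as subregion 3 of 5; the annulus as the voxel-pooled subregions 1 and 5.
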