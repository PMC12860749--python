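# marrowquant

Quantification of bone-marrow involvement in the appendicular skeleton from
low-dose CT and [18F]FDG-PET volumes, plus a synthetic phantom generator that
provides ground-truth cohorts for validation.

## What it does

- **phantom** — synthetic long-bone CT phantoms (cortical shell > 120 HU,
  fatty marrow in [-200, -30] HU, infiltrated marrow in (-30, 120] HU, with
  diffuse/focal/mixed infiltration patterns), matched PET volumes with
  liver/mediastinum/skull reference regions, and paired baseline/follow-up
  cohorts with planted treatment effects, clinical covariates and MRD labels.
- **ct_marrow** — HU tissue classification; the *manual* CT value (CTv):
  highest mean HU over an exhaustive sweep of circular ROIs in the medullary
  cavity; the *semi-automated* cumulative CT value (cCTv): mean HU of
  infiltrated voxels weighted by the infiltrated-to-cavity volume ratio.
- **pet_metrics** — body-weight SUV conversion, VOI max/mean/median
  statistics, nearest-neighbor mask resampling between grids.
- **impetus** — five-point Deauville scoring against mediastinum/liver
  references, focal (Fx) and lytic (Lx) lesion count bands, and a JSON
  scoring report with PMD/EMD/fracture flags.
- **volumetrics** — whole-skeleton metabolic tumor volume (MTV) at the
  liver-SUVmedian threshold (inclusive) with skull exclusion and optional
  spillover erosion; total lesion glycolysis TLG = SUVmean x MTV.
- **cohort_stats** — Spearman, Wilcoxon rank-sum/signed-rank,
  Kruskal-Wallis, chi-square association, Cohen's kappa, and a configurable
  statistics panel over cohort tables (unadjusted p-values, alpha = 0.05).
- **io / cli / pipeline** — NIfTI-1 volume and label-map I/O, validated
  YAML/JSON configuration, and a deterministic end-to-end driver.

## CLI

```sh
marrowquant phantom     --config examples/demo.yaml --out scratch/ph --seed 1
marrowquant quantify-ct --ct ct.nii --masks ct_masks.nii --radii 3,4,5,6 --out ct.json
marrowquant quantify-pet --pet pet.nii --masks pet_masks.nii --out suv.json
marrowquant impetus     --stats suv.json --counts counts.json --out report.json
marrowquant mtv         --pet pet.nii --masks pet_masks.nii --out mtv.json
marrowquant stats       --cohort cohort.csv --panel panel.yaml --out results.csv
marrowquant run         --config examples/demo.yaml --out scratch/demo --seed 1
```

Masks travel as a single NIfTI label map (codes in `marrowquant.io.LABEL_CODES`:
1 medullary_cavity, 2 epiphysis, 3 cortical, 4 infiltration, 5 skeleton,
6 skull, 7 liver, 8 mediastinum, 9 lesions; nested structures are stored with
the inner code and containment is restored on read).

The demo config (`examples/demo.yaml`, 10 patients, 64^3 grids) runs the whole
chain — phantom, CTv/cCTv, SUV VOIs, Deauville, MTV/TLG, statistics panel — in
a few seconds on one CPU and is byte-for-byte reproducible under a fixed seed.

## Conventions and documented interpretation choices

- cCTv default reading: `sum(HU over infiltrated voxels) * voxel_volume /
  cavity_volume` (HU units); a `literal` reading (raw HU sum times the volume
  ratio) is selectable via `compute_cctv(..., interpretation="literal")`.
- Deauville gap: the interval (liver, liver + 10%] is not claimed by the
  printed rules; it scores 3 by default (`gap_score` configurable), and
  "twice liver" bounds score 4 at 2 x liver SUVmean.
- Target VOIs are compared by SUVmax against reference SUVmean (both
  configurable); MTV threshold inclusion is `>=`.
- HU bands are half-open so classification is a partition:
  fat [-200, -30], infiltrated (-30, 120], cortical (120, inf).
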