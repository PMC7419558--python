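# tomotex

Simulated digital breast tomosynthesis (DBT) imaging and texture–perception
analysis: a configurable, tested pipeline that generates voxelized
compressed-breast phantoms, simulates noisy limited-arc X-ray projections,
optionally denoises them with a space-variant adaptive Wiener filter,
reconstructs 1-mm slabs with Feldkamp filtered back projection plus 3D
Butterworth apodization, extracts 13 second-order texture features (GLCM,
NGTDM, RLM) over lattice ROIs, scores detection–localization performance
(LROC AUC via the Wilcoxon statistic) with a parametric synthetic observer,
and correlates per-condition texture means with observer AUC.

## Layout

| module | role |
| --- | --- |
| `tomotex.phantom` | procedural compressed-breast phantoms (seeded Voronoi compartments, skin rind, ligament sheets), spherical lesion insertion, VGF measurement |
| `tomotex.projector` | Siddon ray tracing, Beer–Lambert projection with a source spectrum, detector gain/blur/Poisson/electronic-noise cascade, per-view dose split |
| `tomotex.wiener` | space-variant adaptive Wiener filter and robust noise-variance estimation |
| `tomotex.recon` | ramp-filtered Feldkamp back projection, 3D Butterworth filter, 1-mm slab extraction, breast masks |
| `tomotex.texture` | quantization, lattice ROIs, GLCM/NGTDM/RLM matrices and the 13 named features, per-condition aggregation |
| `tomotex.lroc` | sessions, localization scoring, localization-corrected Wilcoxon AUC, parametric synthetic observer |
| `tomotex.correlate` | Pearson correlation of feature means with AUC, highlighting rule, concavity classification |
| `tomotex.study` | study configuration, image-inventory bookkeeping, staged on-disk pipeline, reduced-scale trend experiment |
| `tomotex.cli` | `tomotex` command-line interface |

## CLI

```bash
tomotex inventory                 # slab-count arithmetic of the default design
tomotex run --scale --out out/    # full staged study at desk scale
tomotex phantom --vgf 0.25 --shape 64 64 50 --voxel 1.0 --seed 1 --out ph.nii
tomotex project --phantom ph.nii --projections 11 --wiener --out proj.tif
tomotex recon --projections proj.tif --phantom ph.nii --out vol.nii
tomotex score --trials trials.csv # LROC AUC from a trial CSV (works for human data too)
tomotex report --root out/        # summarize a completed study directory
```

Stages are resumable: a rerun of `tomotex run` skips completed stages.

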