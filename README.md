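# ctnodes

Dose-robustness analysis of automated lymph-node detection and segmentation
on body CT.

Automated segmenters for lymph nodes are trained and validated on standard
(full-dose) CT, but much of clinical imaging — PET/CT attenuation scans,
surveillance of patients with high cumulative exposure — is acquired at a
fraction of that dose, where quantum noise degrades small-structure
conspicuity. `ctnodes` provides the three ingredients needed to quantify
that effect for any segmenter that produces lesion masks:

1. **Reduced-dose simulation** (`ctnodes.dose`). From a full-dose volume it
   estimates an image-specific noise model — the per-voxel noise magnitude
   σ_full (via the median absolute deviation of a high-pass residual,
   corrected for the noise texture) and the radial noise power spectrum
   (NPS) — then synthesizes noise the way a scanner would: white noise in
   the sinogram domain, per-projection filtering with an NPS-matched
   apodized ramp, parallel-beam backprojection, and dose-dependent scaling.
   A dose fraction *d* adds noise with σ_add = σ_full·√(1/d − 1), so total
   variance follows the mA-proportional quantum law σ²(d) = σ_full²/d;
   *d* = 1 returns the input bit-identically. Anatomy is unchanged, so
   full-dose reference masks remain valid at every dose.
2. **Lesion-wise evaluation** (`ctnodes.metrics`). Connected components
   (26-connectivity) are the unit of detection. Each reference node is sized
   by its short-axis diameter — SAD, the largest inscribed-circle diameter
   on any axial slice — and stratified: ignored (< 3 mm), small (3–8 mm),
   large (≥ 8 mm). A node is a TP when a predicted component overlaps it;
   precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic
   mean. Segmentation quality is scored with the Dice coefficient
   2|A∩B|/(|A|+|B|) and the 95th-percentile symmetric surface distance
   (HD95, mm), per volume and per node.
3. **Dose-response statistics** (`ctnodes.stats`). One-way repeated-measures
   ANOVA across dose levels (Greenhouse–Geisser corrected), paired Wilcoxon
   signed-rank post-hocs with Bonferroni adjustment, and an OLS fit of each
   metric against ln(dose) with its R².

`ctnodes.phantom` generates body-CT-like phantoms (soft-tissue background,
organ blobs, dozens of quasi-ellipsoidal nodes with log-normal SADs) plus
controlled mask perturbations, so the whole pipeline is testable without
patient data. `ctnodes.pipeline` orchestrates volume × dose grids behind one
seeded, fully reproducible configuration, with a built-in noise-adaptive
threshold ("toy") segmenter or externally produced prediction masks (e.g.
nnU-Net output) read from NIfTI.

## Worked example

```python
import numpy as np
from ctnodes import (PhantomSpec, generate_phantom, estimate_noise,
                     simulate_reduced_dose, toy_segment, evaluate_volume)

vol, ref, table = generate_phantom(PhantomSpec(seed=3))
model = estimate_noise(vol)
print(f"sigma_full = {model.sigma_full:.1f} HU")

for d in (1.0, 0.25, 0.05):
    reduced = simulate_reduced_dose(vol, d, model, seed=7)
    ev = evaluate_volume(ref, toy_segment(reduced))
    c = ev.match.counts["all"]
    print(f"d={d:4.2f}  TP={c.tp:2d} FP={c.fp:2d} FN={c.fn:2d}  "
          f"DSC={ev.volume_dsc:.3f}")
```

prints

```
sigma_full = 9.7 HU
d=1.00  TP=10 FP= 0 FN= 2  DSC=0.799
d=0.25  TP= 9 FP= 0 FN= 3  DSC=0.604
d=0.05  TP= 7 FP= 2 FN= 5  DSC=0.385
```

The phantom has 12 eligible nodes. At full dose the segmenter already
misses the two faintest, small ones; at 5% dose the injected noise has
σ ≈ 9.7·√19 ≈ 42 HU and the noise-adaptive threshold sacrifices further
small, low-contrast nodes, so sensitivity and Dice both fall — the
qualitative signature this package exists to measure.

The same experiment over many volumes, with tables and statistics, is one
call (or `ctnodes run-all out/ --n-phantoms 20`):

```python
from ctnodes import RunConfig, run_experiment
result = run_experiment(RunConfig(n_phantoms=20, master_seed=1,
                                  output_dir="out"))
```

which writes `detection_table.csv`, `segmentation_table.csv`, per-volume and
per-node CSVs, `stats_report.json` and a seed manifest.

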