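# atlasmaker

Digital 3D-atlas construction from multi-channel confocal z-stacks of
developing embryos — built for quantitative studies of neuronal
differentiation patterns (e.g. the zebrafish hindbrain), where many
embryos, imaged with anisotropic voxels and segmented by several human
annotators, must be fused into one representative, quantifiable 3D model.

## What it does

The pipeline mirrors how such atlases are built at the bench:

1. **Rigid registration.** Each embryo's pan-neuronal reference channel
   (HuC) is aligned to a chosen reference stack by a 2+2 schedule of
   coarse (phase-correlation translation + rotation scan on a pyramid) and
   subpixel (continuous 6-parameter optimization) steps maximizing
   normalized cross-correlation over the overlap region. The recovered
   transform is reused on the signal-of-interest channel.
2. **Trainable voxel segmentation.** Per-user classifiers (a random
   decision forest on local mean/variance features at radii {1, 2, 4})
   are trained from sparse foreground/background brush strokes and applied
   to whole stacks, giving one binary mask per user per embryo. A one-way
   ANOVA across a panel of specimens plus a 10% relative-deviation rule
   flags outlier users, whose classifiers are discarded.
3. **Consensus fusion.** Per-user masks are vote-counted into per-embryo
   consensus masks, and per-embryo masks into a *label 3D-model*
   (default: signal present in ≥ 3 embryos). An imprint diagnostic —
   overlap of the k-thresholded signal with the hole it carves in the
   reference domain — supports threshold selection.
4. **Quantification.** Volumes (voxel count x voxel volume, um³),
   virtual-reslice profiles of signal/reference ratio along the AP/ML/DV
   axes, local-linear Epanechnikov kernel smoothing
   (K(u) = 0.75 (1 − u²) on |u| ≤ 1) with leave-one-out cross-validated
   bandwidth, and percent deviation of individuals from the model.
5. **Birthdating.** Time-ordered photoconversion masks (green→red
   converted reporter marks all neurons differentiated before conversion)
   are differenced into an interval-labeled map partitioning the
   differentiation domain by birth date; populations are intersected with
   the map to get per-interval volume fractions.
6. **Shape comparison.** Binary models become triangulated surfaces
   (anti-aliased marching cubes, physical um); two conditions are compared
   by sampling ~400,000 points on the reference surface and measuring the
   signed point-to-triangle distance to the comparison surface (positive
   where the comparison lies outside the reference solid).

A phantom generator (bent elliptical tube with a dorsal notch, striped
sub-domains, nested birthdate shells, simulated per-user boundary noise
and per-embryo rigid/shape jitter) provides ground truth for every stage,
so the whole pipeline is testable without any imaging data.

## Worked example

```python
import numpy as np
from atlasmaker import (
    make_neural_tube_phantom, simulate_user_segmentations, average_masks,
    threshold_consensus, mask_volume, variability_to_model, dice,
    build_birthdate_map, interval_growth_table,
)

# two-channel phantom with known truth
(ch1, ch2), truth = make_neural_tube_phantom(shape=(64, 64, 64), seed=0)
domain = truth.total_domain
print(f"phantom domain volume: {mask_volume(domain):.1f} um^3")

# five simulated raters, 20% boundary flips, fused by majority vote
users = simulate_user_segmentations(domain, n_users=5, boundary_flip_rate=0.2, seed=1)
consensus = threshold_consensus(average_masks(users), k=3)
print(f"single-rater Dice: {np.mean([dice(u, domain) for u in users]):.3f}")
print(f"3-of-5 consensus Dice: {dice(consensus, domain):.3f}")

# interindividual variability of rater volumes against the consensus model
table, mean_dev = variability_to_model(
    [mask_volume(u) for u in users], mask_volume(consensus))
print(f"mean deviation from model: {mean_dev:.2f}%")

# birthdate map from the nested shells (photoconversions at 24 and 48 hpf)
s1, s2, s3 = truth.shells
bmap = build_birthdate_map([s1, s2], total=s3, times_hpf=[24, 48], acquisition_hpf=72)
print(interval_growth_table(bmap)[["interval", "volume_um3", "cumulative_ratio"]]
      .to_string(index=False))
```

prints

```
phantom domain volume: 28321.5 um^3
single-rater Dice: 0.946
3-of-5 consensus Dice: 0.984
mean deviation from model: 0.49%
interval   volume_um3  cumulative_ratio
 0-24hpf  8497.376118          0.300033
24-48hpf  8496.602856          0.600038
48-72hpf 11327.515038          1.000000
```

Consensus fusion beats every individual rater (Dice 0.984 vs 0.946), the
rater volumes sit within half a percent of the fused model, and the
birthdate intervals recover the generated 30/30/40% shell mix of the
phantom. Volumes are in um³ at the phantom's confocal-like spacing of
0.57 x 0.57 x 1.19 um per voxel.

## Command line

Every stage is also exposed as a subcommand of `atlasmaker`:

```bash
atlasmaker simulate --n-embryos 5 --n-users 5 --seed 0 --out-dir fixtures/
atlasmaker register --fixed ref.tif --moving emb.tif \
    --apply-to emb_ch2.tif --out-transform t.txt --out reg.tif
atlasmaker segment --stack s.tif --annotations ann.csv --scales 1,2,4 --out mask.tif
atlasmaker consensus --masks 'emb*/user*.tif' --embryo-k 3 --out model.tif
atlasmaker quantify --signal s.tif --reference huc.tif --axis AP --smooth cv --out profile.csv
atlasmaker birthdate --total huc72.tif --conv p24.tif,p48.tif --times 24,48 \
    --acquisition 72 --out map.tif --table intervals.csv
atlasmaker shape --reference ctrl.tif --comparison treated.tif --out-mesh diff.obj
atlasmaker run --config atlas.yaml       # full config-driven build
```

Stacks are multi-page TIFF or NRRD; masks are 8-bit {0, 255}; transforms
are plain-text 4x4 matrices in um; meshes are OBJ; all tables are CSV.

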