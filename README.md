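# mcsquant

Quantification of membrane contact sites (MCS) between organelles in 2D
electron-microscopy images, starting from segmentation masks produced by any
segmenter (deep network or manual annotation). It is aimed at cell biologists
measuring ER–mitochondria or lipid-droplet–mitochondria apposition: given a
mitochondria instance mask and an ER region mask on the same pixel grid, it
reports how much of the mitochondria boundary is in contact with the ER,
resolved into 10-nm contact-width bins, together with organelle morphometrics
(count, perimeter, area, elongation), segmentation-agreement metrics, and the
hard-example loss reductions used when retraining a detector.

## The contact-width profile

Work at the analysis standard of 1,024 × 1,024-pixel patches at 10 nm/px.
With `Edge(·)` the inner boundary of a binary mask (foreground pixels with a
4-neighbor in the background, or on the image border) and `T` the contact
threshold in pixels (default 10, i.e. 0–100 nm):

1. `overlap = Mito ∧ ER`; overlap pixels are excluded from all candidate sets.
2. For every non-overlap ER edge pixel *e*:
   `MinDistance(e) = min { ‖e − m‖₂ : m ∈ Edge(Mito) \ overlap, ‖e − m‖₂ ≤ T }`,
   sentinel `T + 1` when the set is empty.
3. For every non-overlap mitochondria edge pixel *m*:
   `D(m) = min { ‖m − e‖₂ : e admissible }`, where *e* is admissible iff
   `‖m − e‖₂ < MinDistance(e) + 1`. This near-one-to-one rule encodes that a
   tethering site on one membrane pairs with a unique site on the other,
   relaxed by one pixel because true sites (1–2 nm) are far below the 10-nm
   pixel grid.
4. Mitochondria edge pixels inside the overlap get `D(m) = 0`.
5. A pixel contacts iff `⌈D(m)⌉ ≤ T`; width bin `b = ⌈D(m)⌉` (bin 0 = overlap).
6. The per-bin contact ratio is `length_per_bin[b] / len_mito`, with
   `len_mito = |Edge(Mito)|`. Per image, ratios are recomputed from the sums
   over patches (sum-then-ratio), never averaged over patches.

Elongation is `p² / (4π · area)` with `p` the boundary-pixel count. A
windowless brute-force implementation (`brute_force_contact`) reproduces the
whole profile by exhaustive all-pairs enumeration and anchors the test suite.

## Worked example

Generate a seeded synthetic scene (disk/blob mitochondria, ribbon ER) in the
formats the pipeline reads, then quantify it:

```bash
mcsquant synth --scene random-blobs --seed 4 --size 160 --n-mito 5 \
    --er-density 0.8 --out scene
mcsquant quantify --mito scene/mito.png --er scene/er.png \
    --pixel-nm 10 --patch-size 96 --seed 7 --out out
```

which prints

```
image: 17 instances, len_mito=613 px, cumulative ratio (bins 0-3) = 0.1044
```

i.e. across the 5 random 96-px patches the per-image aggregate saw 17
mitochondria instances (instances are counted per patch, so one
mitochondrion can contribute to several patches), 613 px of mitochondria
boundary, of which 10.44% lies within 30 nm of the ER (bins 0–3: overlap
plus 1–3 px). `out/report.csv` holds one row per patch plus the aggregate
row, with per-bin contact lengths `len_bin_0..10` and ratios
`ratio_bin_0..10`; `out/overlay_patch_*.png` paint each contacting boundary
pixel with its width-bin color. For tissue samples, add
`--mode tissue --roi annotations.json`: patches are then kept only if the
annotated cell territory covers more than 15% of their area.

The same operations are available as a library:

```python
import mcsquant as mq
mito, er, expected = mq.parallel_bar_scene(gap_px=2, height=20, threshold=10)
profile, dmap, edge = mq.contact_pipeline(mito, er, 10)
profile.length_per_bin        # array([ 0, 0, 0, 20, 0, 0, 0, 0, 0, 0, 0])
mq.contact_ratio(profile).at(3)  # 1.0 — every boundary pixel contacts at 30 nm
```

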