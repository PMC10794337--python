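# macromorph

Single-cell morphology profiling of polarized human macrophages:
segmentation of fluorescence micrographs, a seven-descriptor shape
panel, class-balanced **SuperTiles** data augmentation, and
random-forest models that classify six macrophage phenotypes — or
predict intracellular IL-10 content — from cell shape alone.

## The problem

Macrophages polarize into functionally distinct phenotypes (M0
unstimulated; GM-CSF-M1 and GM-CSF/TNFα/IFNγ-M1 pro-inflammatory;
M-CSF-M2, M-CSF/IL-4-M2a and M-CSF/IL-10-M2c anti-inflammatory
subtypes). Their shape tracks their state: activated M1 cells elongate,
M2 subtypes stay rounder and more compact. From DAPI (nucleus) and
phalloidin (F-actin) channels, each cell is segmented and reduced to

| descriptor | definition |
|---|---|
| area | pixel count · pixel_size², µm² |
| major / minor axis | moment-equivalent ellipse axes, µm |
| circularity | 4π·area / perimeter², clamped ≤ 1 |
| aspect ratio | major / minor (elongation) |
| roundness | 4·area / (π·major²) = minor/major for an ellipse |
| solidity | area / convex-hull area |

plus marker intensities (CD80, CD163, intracellular IL-10) measured as
raw integrated intensity over the cell mask, background-subtracted and
normalized to a linear fluorescent-bead standard curve so values are
comparable across exposure times.

Single-cell descriptor distributions of the six classes overlap
heavily, so a random forest on individual cells barely beats chance.
The SuperTiles algorithm averages `t` randomly chosen same-class rows
into one synthetic row and balances every class to

```
n_tiles_per_class = floor(n_minority_class · s / t)
```

(`s` = sample time / bootstrap factor). Averaging contracts
within-class variance by ≈ 1/t while preserving class means, which
turns the overlapping single-cell problem into a cleanly separable
tile-level one — the mechanism behind the jump from ~30–40% to >90%
classification accuracy as `t` grows.

The study's raw images are not deposited, so the package ships a
first-class synthetic-data module (`macromorph.synthdata`) that
generates annotated scenes (perturbed-ellipse cells with nucleus, actin
and marker channels) and tabular cohorts with the study's structure:
the six classes at their unbalanced sizes (353/3078/1891/1321/1077/1584
cells = 9304 in total, 3 donors), overlapping shape distributions, and
marker intensities coupled to morphology. Every downstream stage is
tested against this generator's analytic ground truth.

## Worked example

```python
from macromorph import synthdata
from macromorph.modeling import ModelConfig, run_experiment
from macromorph.supertiles import SuperTileParams

specs = synthdata.dataset1_class_specs()        # the six-phenotype cohort
cohort = synthdata.make_tabular_cohort(specs, seed=1)   # 9304 cells

orig = run_experiment(cohort, "classify_all", ModelConfig(seed=1),
                      source="original", with_cv=False)
tiles = run_experiment(cohort, "classify_all", ModelConfig(seed=1),
                       source="supertiles", eval_on="synthetic_split",
                       tile_params=SuperTileParams(t=40, s=5, seed=1),
                       with_cv=False)
print(orig["report"].summary())
print(tiles["report"].summary())
```

prints (70/30 held-out test metrics):

```
metric      value          metric      value
------------------        ------------------
accuracy    0.4069        accuracy    0.9750
auc         0.7554        auc         0.9996
recall      0.3275        recall      0.9753
precision   0.3518        precision   0.9753
f1          0.3336        f1          0.9753
kappa       0.2245        kappa       0.9700
mcc         0.2265        mcc         0.9700
```

left: a forest on raw single cells is stuck near chance for the
unbalanced six-class problem; right: the same cohort after SuperTiles
aggregation at t=40, s=5 is almost perfectly separable. Regressing
IL-10 intensity on morphology alone
(`run_experiment(cohort, "regress_il10", ...)`) reaches test
R² ≈ 0.94 — the generator couples IL-10 to cell area, major axis and
aspect ratio at a 5% noise share, and permutation attribution recovers
exactly those three as the top-ranked features.

A shell interface wraps the same stages:

```bash
macromorph run-all --seed 7 --out runs/demo
macromorph train --seed 7 --out runs/demo --task classify --source supertiles --t 40 --s 5
```

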