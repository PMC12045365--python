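# peristroma

Spatial statistics for segmented tumor histology: does proliferation
concentrate in **peristromal niches**?

In xenograft studies of targeted therapy (e.g. ALK inhibitors in ALK+
NSCLC), tumor cells adjacent to ECM-rich stroma are partially sheltered
from the drug's cytostatic effect.  The histological signature is a shift
of proliferating (BrdU+) tumor cells toward stroma.  `peristroma`
quantifies that shift from segmentation-platform exports — cell centroids
classified as BrdU+/BrdU− tumor cells, stroma polygons or masks, and
necrosis masks — on whole cross-sections of 10³–4·10⁵ cells.

## Method

For a cross-section with tumor cells *i = 1…N* (of which *K* are
marker-positive) and a rasterized stroma mask:

1. **Distance profile.** Each cell gets *dᵢ*, the exact Euclidean distance
   (µm) from its pixel center to the nearest stroma pixel.
2. **Digital-avatar null.** An avatar keeps every cell position and the
   stroma geometry but redistributes the *K* positive labels uniformly
   among the *N* cells.  Because a uniformly random size-*K* subset has
   expected ECDF equal to the all-cell ECDF, the expected null curve and
   the null median/mean are available in closed form; an *R*-replicate
   avatar ensemble supplies null bands and the add-one empirical p-value
   *p = (1 + #{null ≤ observed}) / (R + 1)* (left tail = proximity bias).
3. **Statistics.** Per sample: the two-sample KS statistic
   *D = supₜ |F₊(t) − F(t)|* between positive-cell and all-cell ECDFs, and
   the deltas Δmedian, Δmean = observed − null (µm; negative = positives
   sit closer to stroma).  Across samples: a paired two-tailed t-test of
   observed vs predicted within a group, and the model × condition
   interaction term of a two-way ANOVA between two host models.

A synthetic-tissue generator (strand-like stroma, uniform cell placement,
exponential distance-dependent labeling with length scale λ; λ=∞ is
exactly one avatar draw) provides ground-truth data for calibration and
power studies.

## Worked example

```python
import numpy as np
from peristroma import (SyntheticConfig, generate_dataset, cell_distances,
                        expected_null_summary, null_ensemble, empirical_pvalue)

sample, _ = generate_dataset(SyntheticConfig(seed=7, bias_length=10.0))
profile = cell_distances(sample)
observed = float(np.median(profile.positive_distances))
null_median, _ = expected_null_summary(profile)
ens = null_ensemble(profile, r=999, seed=1)
print(observed, null_median, empirical_pvalue(observed, ens.medians, "left"))
```

Running `python examples/03_avatar_null.py` (the same computation) prints:

```
observed positive median:   5.00 µm
expected null median:       21.39 µm (closed form, all cells)
avatar 95% null band:       [17.97, 25.06] µm  (R=999)
delta (observed - null):    -16.39 µm
left-tail empirical p:      0.0010
```

The positives' median distance (5.0 µm) lies far below the avatar null
band around 21.4 µm: proliferating cells are concentrated against the
stroma, and no more extreme median occurred in any of the 999 avatars
(p at the 1/(R+1) floor).  The other scripts in `examples/` cover
simulation (`01`), distance profiles and KS comparison (`02`), and
group-level paired/interaction tests (`04`).

A thin CLI wraps the same library calls:

```bash
peristroma simulate --seed 7 --bias-length-um 10 --out bundle/
peristroma analyze --bundle bundle/ -R 999 --seed 1 --out results/
peristroma compare results/summary.json ... --out group/
```

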