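"""The digital-avatar permutation null and the empirical p-value.

An avatar keeps every cell position and the stroma geometry, and
redistributes the marker labels uniformly among the tumor cells with the
positive fraction preserved.  The observed positive-cell median distance
is referred to the ensemble of avatar medians; the add-one left-tail
p-value asks how often chance alone puts positives at least this close
to stroma.
"""

import numpy as np

from peristroma import (
    SyntheticConfig,
    cell_distances,
    empirical_pvalue,
    expected_null_summary,
    generate_dataset,
    null_ensemble,
)

sample, _ = generate_dataset(SyntheticConfig(seed=7, bias_length=10.0))
profile = cell_distances(sample)

observed = float(np.median(profile.positive_distances))
null_median, null_mean = expected_null_summary(profile)
ensemble = null_ensemble(profile, r=999, seed=1)
p = empirical_pvalue(observed, ensemble.medians, tail="left")
lo, hi = np.quantile(ensemble.medians, [0.025, 0.975])

print(f"observed positive median:   {observed:.2f} µm")
print(f"expected null median:       {null_median:.2f} µm (closed form, all cells)")
print(f"avatar 95% null band:       [{lo:.2f}, {hi:.2f}] µm  (R=999)")
print(f"delta (observed - null):    {observed - null_median:+.2f} µm")
print(f"left-tail empirical p:      {p:.4f}")
# A negative delta far outside the null band, with p at the 1/(R+1)
# floor, is the signature of proliferation biased toward the
# peristromal niche.
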