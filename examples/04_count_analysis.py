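"""Deterrent effect on bat activity: block-design count analysis.

Bat passes are counted per 5-min block in an alternating control/deterrent
schedule (12 blocks per night, 3 nights at each of 3 sites). A mixed model
with random intercepts for block-in-night-in-site estimates the treatment
rate ratio; the simulation's ground truth is the reported ~27% reduction
for P. pygmaeus.
"""

import numpy as np

from batrack import (CountSimParams, composition_table, fit_count_model,
                     percent_reduction, simulate_counts)
from batrack.stats import SparseDataError

counts = simulate_counts(CountSimParams(seed=42))

table, summary = composition_table(counts)
print("species composition (passes):")
print(table.to_string(index=False))
print(f"total {summary['grand_total']} passes, "
      f"{summary['per_night_mean']:.1f} per night\n")

for species in ("P. pygmaeus", "Myotis spp.", "Nyctalus/Eptesicus"):
    try:
        res = fit_count_model(counts, species)
    except SparseDataError as exc:
        print(f"{species}: {exc}")
        continue
    ratio = float(np.exp(res.coef("treatment[deterrent]")))
    red = percent_reduction(counts, [species], ["pass"], model=res)
    print(f"{species}: {res.family} GLMM, rate ratio {ratio:.2f} "
          f"(raw reduction {red['raw_pct']:.1f}%, "
          f"model {red['model_pct']:.1f}%), "
          f"LRT p = {res.lrt_treatment['p']:.2g}")
# The rate ratio estimates centre on the simulated reductions; sparse
# groups (too few passes per night) are refused rather than over-fitted.
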