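"""The shift-detection toolbox on synthetic series: STARS, PCA, CC, traffic light.

Generates a multivariate series with a planted 1989 break, then shows the
four detectors the pipeline chains together.
"""

import numpy as np
import pandas as pd

from enashift import (
    CcConfig,
    StarsConfig,
    chronological_clustering,
    coefficient_of_variation,
    make_block_series,
    pca_index,
    stars,
    stars_on_scores,
    traffic_light,
)

m = make_block_series(15, 18, mean_shift=3.0, n_vars=5, noise_sd=1.0, seed=1,
                      start_year=1974)

r = stars(m["var1"], StarsConfig(alpha=0.05, cutoff=5, huber=3.0))
print(f"STARS on var1: shifts {r.shift_years}, "
      f"RSI {[round(float(v), 2) for v in r.rsi.values()]}")

p = pca_index(m)
print(f"PCA: PC1 explains {p.variance_explained[0]:.0f}% of variance "
      f"(a shared break loads everything on PC1)")
print(f"STARS on PC1 scores: shifts {stars_on_scores(p, 1).shift_years}")

part = chronological_clustering(m, CcConfig(alpha=0.01, connectedness=0.5,
                                            permutations=999, seed=0))
print(f"chronological clustering segments: {part.segments}")

tl = traffic_light(m, ordering=p.loadings["PC1"])
print("traffic-light categories (1 low ... 5 high), first variable:")
print("  " + "".join(str(c) for c in tl.categories.iloc[0]))

# CV is SD/|mean|, so shift the toy series to a positive baseline first
cv = coefficient_of_variation(m["var1"] + 10.0, [(1974, 1988), (1989, 2006)])
for period, v in cv.items():
    print(f"CV {period[0]}-{period[1]}: {v:.3f}")
print("\nAll four views agree on the 1989 discontinuity; the CV quantifies")
print("relative variability within each regime.")
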