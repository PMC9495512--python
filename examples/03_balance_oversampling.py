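"""Compare the three minority oversamplers on an imbalanced toy cloud.

Shows what each method does geometrically: SMOTE interpolates everywhere,
Borderline-SMOTE seeds only points near the class boundary, ADASYN
allocates adaptively and jitters the result off the interpolation lines.
"""

import numpy as np

from msres import BalanceConfig, balance_training_set
from msres.balance import danger_set

rng = np.random.default_rng(0)
minority = rng.normal(loc=0.0, scale=1.0, size=(40, 2))
majority = rng.normal(loc=2.0, scale=1.0, size=(400, 2))
X = np.vstack([minority, majority])
y = np.r_[np.ones(40, int), np.zeros(400, int)]

print(f"before balancing: {np.bincount(y)[1]} minority / {np.bincount(y)[0]} majority")
mask = danger_set(minority, majority, 5)
print(f"borderline (DANGER) minority points: {mask.sum()} of {len(minority)}")

for method in ("smote", "borderline_smote", "adasyn"):
    Xb, yb = balance_training_set(X, y, BalanceConfig(method, seed=1))
    synth = Xb[len(X):]
    print(f"{method:>16}: +{len(synth)} synthetic -> classes {np.bincount(yb)}, "
          f"synthetic centroid {synth.mean(axis=0).round(2)}")

# With sampling_strategy = 1 every method raises the minority count to the
# majority count (440 total per class here); the centroids show where each
# method concentrates its synthetic mass.
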