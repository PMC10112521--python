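"""Normalize raw signals and derive the experiment-wide bmad.

A 75-fold luminescence gain over plate baseline is 6.23 in log2 units —
the magnitude of the positive-control response — and the percent map for
antagonist mode sends the baseline to 0 and the positive control to 100.
"""

import numpy as np

from arscreen.assay_data import WellRecord
from arscreen.normalization import (
    PlateNormalizationStats,
    compute_bmad,
    normalize_plate,
)

stats = PlateNormalizationStats("P1", bval=1000.0)


def well(signal, mode="agonist"):
    return WellRecord("P1", "A01", "test", "chem", 1.0, mode, "mock", signal)


for fold in (75, 2.17):
    resp = normalize_plate([well(1000.0 * fold)], stats, "agonist")[0].resp
    print(f"{fold:>5}-fold signal -> log2 resp = {resp:.2f}")

pstats = PlateNormalizationStats("P1", bval=700000.0, pval=10000.0)
for signal, label in ((10000.0, "pval"), (700000.0, "bval")):
    resp = normalize_plate([well(signal, "antagonist")], pstats,
                           "antagonist")[0].resp
    print(f"antagonist signal at {label} -> resp = {resp + 0.0:.0f}%")

# bmad: the unit of the activity thresholds (5x agonist, 3x antagonist)
rng = np.random.default_rng(0)
vehicle_resps = np.log2(np.exp(rng.normal(0, 0.1, 48)))
bmad = compute_bmad(vehicle_resps)
print(f"bmad over {len(vehicle_resps)} vehicle wells = {bmad:.3f} log2 units "
      f"-> agonist threshold {5 * bmad:.3f}")
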