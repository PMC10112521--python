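"""Cytotoxicity gating of antagonist hits.

Reproduces the two canonical phenotypes: a true antagonist whose inhibition
occurs two log units below its cytotoxicity (gate passed), and a cytotoxic
compound whose apparent inhibition coincides exactly with its viability
loss (confounded, called inactive).
"""

import numpy as np

from arscreen.activity_calls import call_antagonist
from arscreen.assay_data import ExperimentThresholds
from arscreen.hill_fitting import HillFit, hill_response
from arscreen.normalization import ConcentrationSeries, SeriesPoint

thresholds = ExperimentThresholds(bmad_agonist=0.1, bmad_antagonist=5.0,
                                  bmad_viability=5.0)
concs = np.logspace(-3, 2, 11)


def series(top, l10, mode):
    resp = hill_response(concs, top, l10, 2.0)
    return ConcentrationSeries("chem", mode, "mock",
                               tuple(SeriesPoint(float(c), (float(r),), float(r))
                                     for c, r in zip(concs, resp)))


def fit(top, l10):
    return HillFit(top=top, log10_ac50=l10, slope=2.0, rss=0.0,
                   converged=True, n_points=11)


for name, ant_l10, cyt_l10 in [("true antagonist", -1.5, 0.5),
                               ("cytotoxic artifact", -0.5, -0.5)]:
    call = call_antagonist(series(90, ant_l10, "antagonist"),
                           fit(90, ant_l10),
                           series(95, cyt_l10, "viability"),
                           fit(95, cyt_l10), thresholds)
    sep = cyt_l10 - ant_l10
    print(f"{name}: Dlog10(cytotox - antagonist AC50) = {sep:+.1f} -> "
          f"active={call.active}, gating={call.gating}")
# the gate requires the antagonist AC50 to sit >= 0.5 log10 (3.16-fold)
# below the cytotoxicity AC50
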