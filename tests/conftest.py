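"""Shared fixtures: small synthetic campaigns with known ground truth."""

from __future__ import annotations

import pytest

from arscreen import ExperimentThresholds, analyze_experiment
from arscreen.synthetic_plates import (
    ChemicalTruth,
    HillTruth,
    SimConfig,
    simulate_experiment,
)

# hand-picked truths whose potencies sit well inside the tested range and
# whose activity at the two lowest concentrations is negligible, so the
# plate baseline (bval) is unbiased and noiseless recovery is exact
CLEAN_TRUTHS = [
    ChemicalTruth("ag-strong", agonist_params=HillTruth(6.23, -1.0, 1.5)),
    ChemicalTruth("ag-weak", agonist_params=HillTruth(3.5, 0.5, 2.0)),
    ChemicalTruth("ant-clean", antagonist_params=HillTruth(95.0, -0.5, 2.0)),
    ChemicalTruth(
        "ant-gated",
        antagonist_params=HillTruth(90.0, -1.0, 2.0),
        cytotox_params=HillTruth(100.0, 1.0, 3.0),
    ),
    ChemicalTruth("tox-only", cytotox_params=HillTruth(100.0, 0.0, 2.5)),
    ChemicalTruth("dead-inactive"),
]

#: override thresholds for noiseless campaigns, whose bmad degenerates to 0
NOISELESS_THRESHOLDS = ExperimentThresholds(
    bmad_agonist=0.1, bmad_antagonist=5.0, bmad_viability=5.0
)


@pytest.fixture(scope="session")
def zero_noise_campaign():
    cfg = SimConfig(n_test_chemicals=len(CLEAN_TRUTHS), noise_cv=0.0, seed=11)
    exp, truth = simulate_experiment(CLEAN_TRUTHS, cfg)
    return exp, truth


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_campaign):
    exp, _ = zero_noise_campaign
    return analyze_experiment(exp, thresholds=NOISELESS_THRESHOLDS)


@pytest.fixture(scope="session")
def noisy_campaign():
    cfg = SimConfig(n_test_chemicals=len(CLEAN_TRUTHS), noise_cv=0.10, seed=23)
    exp, truth = simulate_experiment(CLEAN_TRUTHS, cfg)
    return exp, truth
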