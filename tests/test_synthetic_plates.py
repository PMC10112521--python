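"""The forward simulator: plate design, noise model, determinism."""

import math

import numpy as np
import pytest

from arscreen.assay_data import validate_experiment
from arscreen.synthetic_plates import (
    ChemicalTruth,
    HillTruth,
    SimConfig,
    sample_truths,
    simulate_experiment,
)
from arscreen.synthetic_plates import test_concentrations as titration_concs


def _simulate(truths, **kw):
    cfg = SimConfig(n_test_chemicals=len(truths), **kw)
    return simulate_experiment(truths, cfg), cfg


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"conc_top_uM": 0.0}, {"dilution_factor": 1.0}, {"noise_cv": -0.1},
        {"n_test_chemicals": 0}, {"modes": ("viability",)},
    ])
    def test_invalid_config_rejected_before_generation(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_titration_spans_half_log_steps(self):
        concs = titration_concs(SimConfig())
        assert len(concs) == 11
        assert concs[-1] == pytest.approx(99.9)
        ratios = concs[1:] / concs[:-1]
        assert np.allclose(ratios, 3.162)


class TestForwardModel:
    def test_inactive_chemical_sits_exactly_at_baseline_without_noise(self):
        (exp, _), cfg = _simulate([ChemicalTruth("null")], noise_cv=0.0,
                                  seed=1, n_replicate_experiments=1)
        test_wells = [w for w in exp.wells
                      if w.chemical_id == "null" and w.mode == "agonist"]
        assert test_wells
        assert all(w.raw_signal == cfg.baseline_rlu for w in test_wells)

    def test_saturating_agonist_matches_positive_control_fold(self):
        # top 6.23 log2 at conc >> AC50 gives ~75x baseline, the
        # positive-control magnitude
        truth = ChemicalTruth("sat",
                              agonist_params=HillTruth(6.23, -2.5, 2.0))
        (exp, _), cfg = _simulate([truth], noise_cv=0.0, seed=1,
                                  n_replicate_experiments=1,
                                  modes=("agonist",))
        top_conc = titration_concs(cfg)[-1]
        (w,) = [w for w in exp.wells
                if w.chemical_id == "sat" and w.conc_uM == top_conc]
        assert w.raw_signal / cfg.baseline_rlu == pytest.approx(2**6.23,
                                                                rel=1e-3)
        assert 2**6.23 == pytest.approx(75, rel=0.01)

    def test_cytotox_coupling_suppresses_antagonist_signal(self):
        tox = ChemicalTruth("tox", cytotox_params=HillTruth(100.0, 0.0, 2.0))
        (exp, _), cfg = _simulate([tox], noise_cv=0.0, seed=1,
                                  n_replicate_experiments=1)
        ant = {w.conc_uM: w.raw_signal for w in exp.wells
               if w.chemical_id == "tox" and w.mode == "antagonist"}
        stim = cfg.baseline_rlu * cfg.positive_fold
        assert ant[min(ant)] == pytest.approx(stim, rel=1e-6)
        assert ant[max(ant)] < 0.01 * stim

    def test_plate_design_passes_validation(self):
        (exp, _), _ = _simulate(sample_truths(40, seed=2), seed=2,
                                biogroups=("mock", "bgal"))
        assert validate_experiment(exp) == []

    def test_cyp_modifier_shifts_truth_ac50(self):
        truth = ChemicalTruth("m", agonist_params=HillTruth(5.0, 0.0, 2.0),
                              cyp_modifiers={"CYP1A2": (8.0, 0.5)})
        eff = truth.params_for("agonist", "CYP1A2")
        assert eff.log10_ac50 == pytest.approx(-math.log10(8))
        assert eff.top == pytest.approx(2.5)
        assert truth.params_for("agonist", "mock") == truth.agonist_params


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        truths = sample_truths(6, seed=5)
        (exp1, t1), _ = _simulate(truths, seed=5)
        (exp2, t2), _ = _simulate(truths, seed=5)
        assert t1 == t2
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        exp1.to_frame().to_csv(a, index=False)
        exp2.to_frame().to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self):
        truths = sample_truths(6, seed=5)
        (exp1, _), _ = _simulate(truths, seed=5)
        (exp2, _), _ = _simulate(truths, seed=6)
        sig1 = [w.raw_signal for w in exp1.wells]
        sig2 = [w.raw_signal for w in exp2.wells]
        assert sig1 != sig2

    def test_duplicate_chemical_ids_rejected(self):
        t = ChemicalTruth("dup")
        with pytest.raises(ValueError, match="duplicate"):
            _simulate([t, t])

    def test_empty_truths_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_experiment([], SimConfig())


class TestPipelineRecovery:
    def test_zero_noise_recovery_within_1e3(self, zero_noise_result,
                                            zero_noise_campaign):
        """Noiseless simulation + full pipeline inverts the forward model."""
        _, truth = zero_noise_campaign
        checked = 0
        for call in zero_noise_result.calls:
            t = truth["chemicals"][call.chemical_id]["mock"]
            endpoint = "agonist" if call.mode == "agonist" else "antagonist"
            if t[endpoint] is None or not call.active:
                continue
            if t["cytotox"] is not None:
                continue  # coupling biases the apparent inhibition curve
            fit = zero_noise_result.fits[
                (call.chemical_id, call.mode, "mock")]
            assert fit.log10_ac50 == pytest.approx(t[endpoint]["log10_ac50"],
                                                   abs=1e-3)
            assert fit.top == pytest.approx(t[endpoint]["top"], rel=2e-3)
            checked += 1
        assert checked >= 3

    def test_noisy_recovery_within_two_tenths_log(self, noisy_campaign):
        from arscreen import analyze_experiment

        exp, truth = noisy_campaign
        result = analyze_experiment(exp)
        errors = []
        for (chem, mode, bg), fit in result.fits.items():
            if mode == "viability" or bg != "mock":
                continue
            t = truth["chemicals"][chem]["mock"][mode]
            if t is None:
                continue
            if truth["chemicals"][chem]["mock"]["cytotox"] is not None:
                continue
            errors.append(abs(fit.log10_ac50 - t["log10_ac50"]))
        assert errors and max(errors) < 0.2
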