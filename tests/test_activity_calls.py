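"""bmad-threshold hit calls and cytotoxicity gating."""

import numpy as np
import pytest

from arscreen.activity_calls import call_agonist, call_antagonist
from arscreen.assay_data import ExperimentThresholds
from arscreen.hill_fitting import HillFit, hill_response
from arscreen.normalization import ConcentrationSeries, SeriesPoint


def _series(concs, meds, mode="agonist", chem="c1"):
    points = tuple(SeriesPoint(float(c), (float(m),), float(m))
                   for c, m in zip(concs, meds))
    return ConcentrationSeries(chemical_id=chem, mode=mode, biogroup="mock",
                               points=points)


def _fit(top=90.0, l10=0.0, slope=2.0, converged=True):
    return HillFit(top=top, log10_ac50=l10, slope=slope, rss=0.0,
                   converged=converged, n_points=11)


def _hill_series(top, l10, slope, mode):
    concs = np.logspace(-3, 2, 11)
    return _series(concs, hill_response(concs, top, l10, slope), mode=mode)


THRESH = ExperimentThresholds(bmad_agonist=0.1, bmad_antagonist=5.0,
                              bmad_viability=5.0)


class TestCallAgonist:
    def test_flat_series_inactive(self):
        call = call_agonist(_series([0.1, 1, 10, 100], [0, 0, 0, 0]),
                            _fit(top=0.0), THRESH)
        assert not call.active and call.ac50_uM is None

    @pytest.mark.parametrize("max_med,expected", [(0.51, True), (0.49, False)])
    def test_five_bmad_boundary_is_strict(self, max_med, expected):
        # bmad 0.1 -> threshold 0.5
        call = call_agonist(_series([0.1, 1, 10, 100], [0, 0.1, 0.3, max_med]),
                            _fit(top=max_med), THRESH)
        assert call.active is expected
        assert call.threshold == pytest.approx(0.5)

    def test_zero_bmad_errors_toward_qc(self):
        broken = ExperimentThresholds(bmad_agonist=0.0, bmad_antagonist=5.0)
        with pytest.raises(ValueError, match="vehicle-well QC"):
            call_agonist(_series([0.1, 1, 10, 100], [0, 0, 0, 1]), _fit(), broken)

    def test_active_call_carries_ac50(self):
        call = call_agonist(_series([0.1, 1, 10, 100], [0, 1, 3, 4]),
                            _fit(top=4.0, l10=0.5), THRESH)
        assert call.active and call.ac50_uM == pytest.approx(10**0.5)


class TestCallAntagonist:
    def _call(self, ant_l10=-1.0, cyt_l10=None, converged=True,
              ant_top=90.0):
        ant = _hill_series(ant_top, ant_l10, 2.0, "antagonist")
        if cyt_l10 is None:
            viab = _series(np.logspace(-3, 2, 11), [0.0] * 11, mode="viability")
            vfit = None
        else:
            viab = _hill_series(95.0, cyt_l10, 2.0, "viability")
            vfit = _fit(top=95.0, l10=cyt_l10)
        return call_antagonist(ant, _fit(top=ant_top, l10=ant_l10,
                                         converged=converged),
                               viab, vfit, THRESH)

    def test_below_threshold_inactive(self):
        call = self._call(ant_top=10.0)
        assert not call.active and call.gating == "not_applicable"

    def test_non_cytotoxic_candidate_stands(self):
        call = self._call(cyt_l10=None)
        assert call.active and call.gating == "not_cytotoxic"

    @pytest.mark.parametrize("delta,active,gating", [
        (2.0, True, "passed"),                       # bicalutamide phenotype
        (0.51, True, "passed"),
        (0.50, True, "passed"),                      # rule is >= 0.5
        (0.49, False, "confounded_by_cytotoxicity"),
        (0.0, False, "confounded_by_cytotoxicity"),  # dichlone phenotype
    ])
    def test_log_separation_boundary(self, delta, active, gating):
        call = self._call(ant_l10=-1.0, cyt_l10=-1.0 + delta)
        assert call.active is active
        assert call.gating == gating

    def test_nonconverged_candidate_deferred(self):
        with pytest.warns(UserWarning, match="deferred"):
            call = self._call(converged=False)
        assert not call.active and "deferred" in call.comment

    def test_bmad_monotonicity_never_flips_inactive_to_active(self):
        series = _hill_series(40.0, -1.0, 2.0, "antagonist")
        viab = _series(np.logspace(-3, 2, 11), [0.0] * 11, mode="viability")
        actives = []
        for bmad in (1.0, 5.0, 10.0, 13.4, 20.0):
            t = ExperimentThresholds(bmad_agonist=0.1, bmad_antagonist=bmad)
            actives.append(call_antagonist(series, _fit(top=40.0, l10=-1.0),
                                           viab, None, t).active)
        # once inactive at some bmad, stays inactive for all larger bmads
        assert actives == sorted(actives, reverse=True)

    def test_gate_antisymmetric_in_the_two_potencies(self):
        confounded = self._call(ant_l10=-0.2, cyt_l10=-1.0)
        assert confounded.gating == "confounded_by_cytotoxicity"
        swapped = self._call(ant_l10=-1.0, cyt_l10=-0.2)
        assert swapped.active and swapped.gating == "passed"


class TestSimulatedCampaignCalls:
    def test_zero_noise_calls_match_ground_truth(self, zero_noise_result,
                                                 zero_noise_campaign):
        _, truth = zero_noise_campaign
        for call in zero_noise_result.calls:
            t = truth["chemicals"][call.chemical_id]["mock"]
            if call.mode == "agonist":
                assert call.active == (t["agonist"] is not None)
            else:
                expected = t["antagonist"] is not None
                assert call.active == expected, call.chemical_id

    def test_confounded_count_equals_cytotox_only_truth(self, zero_noise_result,
                                                        zero_noise_campaign):
        _, truth = zero_noise_campaign
        cytotox_only = {
            chem for chem, t in truth["chemicals"].items()
            if t["mock"]["cytotox"] is not None and t["mock"]["antagonist"] is None
        }
        confounded = {
            c.chemical_id for c in zero_noise_result.calls
            if c.gating == "confounded_by_cytotoxicity"
        }
        assert confounded == cytotox_only

    def test_noisy_calls_recover_clear_actives(self, noisy_campaign):
        from arscreen import analyze_experiment

        exp, truth = noisy_campaign
        result = analyze_experiment(exp)
        by_key = {(c.chemical_id, c.mode): c for c in result.calls}
        assert by_key[("ag-strong", "agonist")].active
        assert by_key[("ant-clean", "antagonist")].active
        assert not by_key[("dead-inactive", "agonist")].active
        assert (by_key[("tox-only", "antagonist")].gating
                == "confounded_by_cytotoxicity")
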