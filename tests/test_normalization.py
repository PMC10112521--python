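"""Plate normalization, bmad, and series aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arscreen.assay_data import WellRecord
from arscreen.normalization import (
    NormalizedWell,
    PlateNormalizationStats,
    aggregate_series,
    compute_bmad,
    compute_plate_stats,
    normalize_plate,
)


def _well(plate="P1", well="A01", role="test", chem="c1", conc=1.0,
          mode="agonist", signal=100.0) -> WellRecord:
    return WellRecord(plate_id=plate, well=well, role=role, chemical_id=chem,
                      conc_uM=conc, mode=mode, biogroup="mock",
                      raw_signal=signal)


def _plate(signals_by_conc, mode="agonist", chem="c1", mec_signals=None):
    wells = []
    i = 0
    for conc, signals in signals_by_conc.items():
        for s in signals:
            wells.append(_well(well=f"A{i+1:02d}", conc=conc, mode=mode,
                               chem=chem, signal=s))
            i += 1
    if mec_signals is not None:
        for j, s in enumerate(mec_signals):
            wells.append(_well(well=f"P{j+1:02d}", role="positive_control",
                               chem="pc", conc=99.8, mode=mode, signal=s))
    return wells


class TestComputePlateStats:
    def test_bval_is_median_of_two_lowest_concs(self):
        wells = _plate({0.1: [9, 10], 0.3: [11, 12], 1.0: [500, 600]})
        stats = compute_plate_stats(wells, "agonist")
        assert stats.bval == 10.5
        assert stats.pval is None

    def test_pval_is_median_of_mec_wells(self):
        wells = _plate({0.1: [800, 800], 0.3: [800, 800]}, mode="antagonist",
                       mec_signals=[195, 200, 200, 205])
        stats = compute_plate_stats(wells, "antagonist")
        assert stats.pval == 200.0

    def test_fewer_than_four_mec_wells_errors(self):
        wells = _plate({0.1: [200], 0.3: [200]}, mode="antagonist",
                       mec_signals=[195, 200, 205])
        with pytest.raises(ValueError, match="minimum four"):
            compute_plate_stats(wells, "antagonist")

    def test_bval_unions_each_chemicals_two_lowest_concs(self):
        # chemicals tested on different ranges: qualifying wells enumerated
        # by brute force over each chemical's own two lowest concentrations
        wells = (
            _plate({0.1: [10.0], 0.3: [20.0], 1.0: [900.0]}, chem="cA")
            + _plate({1.0: [30.0], 3.0: [40.0], 10.0: [900.0]}, chem="cB")
        )
        qualifying = [10.0, 20.0, 30.0, 40.0]  # oracle: per-chemical lowest two
        stats = compute_plate_stats(wells, "agonist")
        assert stats.bval == np.median(qualifying)


class TestNormalizePlate:
    def test_agonist_log2_fold_pairs(self):
        # a 75-fold signal is 6.23 in log2; a 2.17-fold signal is 1.12
        stats = PlateNormalizationStats("P1", bval=100.0)
        wells = [_well(signal=7500.0), _well(well="A02", signal=217.0)]
        resp = [nw.resp for nw in normalize_plate(wells, stats, "agonist")]
        assert resp[0] == pytest.approx(6.23, abs=0.005)
        assert resp[1] == pytest.approx(1.12, abs=0.005)

    def test_agonist_baseline_maps_to_zero(self):
        stats = PlateNormalizationStats("P1", bval=321.0)
        (nw,) = normalize_plate([_well(signal=321.0)], stats, "agonist")
        assert nw.resp == 0.0

    def test_percent_map_endpoints(self):
        stats = PlateNormalizationStats("P1", bval=750000.0, pval=10000.0)
        wells = [_well(mode="antagonist", signal=10000.0),
                 _well(well="A02", mode="antagonist", signal=750000.0)]
        resp = [nw.resp for nw in normalize_plate(wells, stats, "antagonist")]
        assert resp == [100.0, 0.0]

    def test_zero_agonist_signal_flagged_not_raised(self):
        stats = PlateNormalizationStats("P1", bval=100.0)
        (nw,) = normalize_plate([_well(signal=0.0)], stats, "agonist")
        assert nw.flagged and np.isnan(nw.resp)

    @given(gain=st.floats(min_value=0.01, max_value=100.0),
           signal=st.floats(min_value=1.0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_gain_invariance_both_modes(self, gain, signal):
        # multiplying every raw signal by a common gain leaves resp unchanged
        ag0 = normalize_plate([_well(signal=signal)],
                              PlateNormalizationStats("P1", bval=100.0),
                              "agonist")[0].resp
        ag1 = normalize_plate([_well(signal=signal * gain)],
                              PlateNormalizationStats("P1", bval=100.0 * gain),
                              "agonist")[0].resp
        assert ag0 == pytest.approx(ag1, abs=1e-9)
        an0 = normalize_plate([_well(mode="antagonist", signal=signal)],
                              PlateNormalizationStats("P1", bval=500.0,
                                                      pval=100.0),
                              "antagonist")[0].resp
        an1 = normalize_plate([_well(mode="antagonist", signal=signal * gain)],
                              PlateNormalizationStats("P1", bval=500.0 * gain,
                                                      pval=100.0 * gain),
                              "antagonist")[0].resp
        assert an0 == pytest.approx(an1, rel=1e-9, abs=1e-9)


class TestBmad:
    def test_hand_computed_example(self):
        # {-1,0,0,1}: median 0, abs devs {1,0,0,1}, median 0.5, x1.4826
        resps = [-1, 0, 0, 1] * 2  # >= 8 wells required
        assert compute_bmad(resps) == pytest.approx(0.7413)

    def test_identical_responses_warn_and_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_bmad([0.2] * 8) == 0.0

    @given(st.lists(st.floats(-10, 10), min_size=8, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_duplication_and_permutation_invariance(self, resps):
        base = compute_bmad(resps)
        assert compute_bmad(resps[::-1]) == pytest.approx(base, abs=1e-12)
        assert compute_bmad(resps + resps) == pytest.approx(base, abs=1e-12)

    def test_requires_eight_wells(self):
        with pytest.raises(ValueError, match=">= 8"):
            compute_bmad([0.0] * 7)


class TestAggregateSeries:
    def _norm(self, chem, conc, resp, well):
        return NormalizedWell(well=_well(well=well, chem=chem, conc=conc),
                              resp=resp)

    def test_median_per_concentration(self):
        wells = [self._norm("c1", 1.0, r, f"A{i:02d}")
                 for i, r in enumerate([1.0, 2.0, 9.0])]
        (series,) = aggregate_series(wells)
        assert series.points[0].median_resp == 2.0

    def test_pools_replicates_across_plates(self):
        wells = []
        for plate in ("P1", "P2"):
            for i, r in enumerate([1.0, 3.0]):
                wells.append(NormalizedWell(
                    well=_well(plate=plate, well=f"A{i:02d}", conc=1.0),
                    resp=r))
        (series,) = aggregate_series(wells)
        assert len(series.points[0].resps) == 4

    def test_pooled_median_matches_flat_oracle(self):
        rng = np.random.default_rng(3)
        resps = rng.normal(size=12)
        wells = [self._norm("c1", 0.5, r, f"A{i:02d}")
                 for i, r in enumerate(resps)]
        (series,) = aggregate_series(wells)
        assert series.points[0].median_resp == pytest.approx(
            np.median(resps), abs=1e-15)

    def test_sorted_ascending_and_groups_by_key(self):
        wells = [self._norm("c1", 10.0, 1.0, "A01"),
                 self._norm("c1", 0.1, 0.0, "A02"),
                 self._norm("c2", 1.0, 5.0, "A03")]
        series = aggregate_series(wells)
        assert len(series) == 2
        s1 = next(s for s in series if s.chemical_id == "c1")
        assert list(s1.concs) == [0.1, 10.0]
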