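"""Plate normalization and experiment-wide baseline variability (bmad).

Each assay plate contributes its own baseline statistic ``bval`` — the
median raw signal of test-compound wells at each chemical's two lowest
tested concentrations — and, for antagonist and viability plates, a
positive-control statistic ``pval``: the median raw signal of the control
wells at the maximally effective concentration (MEC; minimum four wells).

Agonist responses are log2 fold changes over baseline,
``resp = log2(raw / bval)``, so a well at baseline scores exactly 0 and the
75-fold positive-control response scores log2(75) = 6.23.  Antagonist and
viability responses are percent of the positive-control window,
``resp = 100 * (raw - bval) / (pval - bval)``, an affine map sending bval to
0 and pval to 100.  Both normalizations are invariant to a common gain
applied to every signal on a plate.

The activity thresholds downstream are multiples of ``bmad``: the scaled
median absolute deviation of normalized vehicle (DMSO) responses pooled
across the entire experiment, one value per assay mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .assay_data import MIN_MEC_WELLS, WellRecord, _mec_wells

__all__ = [
    "PlateNormalizationStats",
    "NormalizedWell",
    "SeriesPoint",
    "ConcentrationSeries",
    "compute_plate_stats",
    "normalize_plate",
    "compute_bmad",
    "aggregate_series",
    "mad",
]


def mad(values: Sequence[float], constant: float = 1.4826) -> float:
    """Scaled median absolute deviation.

    ``constant`` defaults to 1.4826, the Gaussian consistency constant used
    by R's ``mad`` (and hence the tcpl lineage of HTS pipelines).
    """
    x = np.asarray(values, dtype=float)
    return float(constant * np.median(np.abs(x - np.median(x))))


@dataclass(frozen=True)
class PlateNormalizationStats:
    plate_id: str
    bval: float
    pval: float | None = None

    def __post_init__(self) -> None:
        if not self.bval > 0:
            raise ValueError(f"plate {self.plate_id}: bval must be > 0")
        if self.pval is not None and self.pval == self.bval:
            raise ValueError(f"plate {self.plate_id}: pval must differ from bval")


@dataclass(frozen=True)
class NormalizedWell:
    """A well plus its normalized response.

    ``flagged`` marks wells whose response is undefined (zero raw signal in
    agonist mode); flagged wells carry ``resp = nan`` and are excluded from
    series aggregation and fitting.
    """

    well: WellRecord
    resp: float
    flagged: bool = False


@dataclass(frozen=True)
class SeriesPoint:
    conc_uM: float
    resps: tuple[float, ...]
    median_resp: float


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-(chemical, mode, biogroup) responses grouped by concentration.

    Points are sorted ascending by concentration; the per-point median pools
    all replicate wells across plates and experiments.
    """

    chemical_id: str
    mode: str
    biogroup: str
    points: tuple[SeriesPoint, ...]

    @property
    def concs(self) -> np.ndarray:
        return np.array([p.conc_uM for p in self.points])

    @property
    def medians(self) -> np.ndarray:
        return np.array([p.median_resp for p in self.points])

    def well_level(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (conc, resp) arrays over all replicate wells."""
        concs, resps = [], []
        for p in self.points:
            concs.extend([p.conc_uM] * len(p.resps))
            resps.extend(p.resps)
        return np.array(concs), np.array(resps)


def _baseline_wells(wells: Iterable[WellRecord]) -> list[WellRecord]:
    """Test wells at each chemical's two lowest tested concentrations."""
    by_chem: dict[str, list[WellRecord]] = {}
    for w in wells:
        if w.role == "test":
            by_chem.setdefault(w.chemical_id, []).append(w)
    qualifying: list[WellRecord] = []
    for chem_wells in by_chem.values():
        lowest_two = sorted({w.conc_uM for w in chem_wells})[:2]
        qualifying.extend(w for w in chem_wells if w.conc_uM in lowest_two)
    return qualifying


def compute_plate_stats(
    plate_wells: Sequence[WellRecord], mode: str
) -> PlateNormalizationStats:
    """Derive per-plate bval (all modes) and pval (antagonist/viability).

    bval is the median raw signal over the union of each test chemical's two
    lowest tested concentrations on the plate.  For antagonist plates pval
    is the median raw signal of the MEC positive-control wells; viability
    plates anchor on the MEC cytotox-control wells instead (full loss of
    viability).  Fewer than four MEC wells is an error.
    """
    if not plate_wells:
        raise ValueError("empty plate")
    plate_id = plate_wells[0].plate_id
    baseline = _baseline_wells(plate_wells)
    if not baseline:
        raise ValueError(f"plate {plate_id}: no test wells to derive bval from")
    bval = float(np.median([w.raw_signal for w in baseline]))
    if mode == "agonist":
        return PlateNormalizationStats(plate_id=plate_id, bval=bval)
    anchor_role = "cytotox_control" if mode == "viability" else "positive_control"
    mec = _mec_wells(plate_wells, anchor_role)
    if len(mec) < MIN_MEC_WELLS:
        raise ValueError(
            f"plate {plate_id}: {len(mec)} MEC {anchor_role} wells; the "
            f"positive-control median requires a minimum four wells"
        )
    pval = float(np.median([w.raw_signal for w in mec]))
    return PlateNormalizationStats(plate_id=plate_id, bval=bval, pval=pval)


def normalize_plate(
    plate_wells: Sequence[WellRecord],
    stats: PlateNormalizationStats,
    mode: str,
) -> list[NormalizedWell]:
    """Apply the mode's normalization to every well on the plate."""
    out: list[NormalizedWell] = []
    for w in plate_wells:
        if w.plate_id != stats.plate_id:
            raise ValueError(
                f"stats are for plate {stats.plate_id}, well is from {w.plate_id}"
            )
        if mode == "agonist":
            if w.raw_signal == 0:
                out.append(NormalizedWell(well=w, resp=float("nan"), flagged=True))
                continue
            resp = float(np.log2(w.raw_signal / stats.bval))
        else:
            if stats.pval is None:
                raise ValueError(f"{mode} normalization requires pval")
            resp = float(
                100.0 * (w.raw_signal - stats.bval) / (stats.pval - stats.bval)
            )
        out.append(NormalizedWell(well=w, resp=resp))
    return out


def compute_bmad(
    vehicle_resps: Sequence[float], mad_constant: float = 1.4826
) -> float:
    """bmad: scaled MAD of normalized vehicle responses, experiment-wide.

    One value per assay mode per screening campaign.  An all-identical input
    yields 0 with a warning — the 5x/3x activity thresholds then degenerate
    and hit calling will refuse to proceed.
    """
    if len(vehicle_resps) < 8:
        raise ValueError(
            f"bmad requires >= 8 vehicle wells, got {len(vehicle_resps)}"
        )
    value = mad(vehicle_resps, mad_constant)
    if value == 0.0:
        warnings.warn(
            "bmad is 0 (identical vehicle responses); activity thresholds "
            "are degenerate",
            stacklevel=2,
        )
    return value


def aggregate_series(
    normalized: Iterable[NormalizedWell],
) -> list[ConcentrationSeries]:
    """Group normalized test wells into per-chemical concentration series.

    Grouping key is (chemical_id, mode, biogroup); each concentration's
    median pools every replicate well across plates and experiments.
    Flagged wells are dropped.  Output order follows first appearance.
    """
    groups: dict[tuple[str, str, str], dict[float, list[float]]] = {}
    for nw in normalized:
        w = nw.well
        if w.role != "test" or nw.flagged:
            continue
        key = (w.chemical_id, w.mode, w.biogroup)
        groups.setdefault(key, {}).setdefault(w.conc_uM, []).append(nw.resp)
    out = []
    for (chem, mode, biogroup), by_conc in groups.items():
        points = tuple(
            SeriesPoint(
                conc_uM=c,
                resps=tuple(by_conc[c]),
                median_resp=float(np.median(by_conc[c])),
            )
            for c in sorted(by_conc)
        )
        out.append(
            ConcentrationSeries(
                chemical_id=chem, mode=mode, biogroup=biogroup, points=points
            )
        )
    return out
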