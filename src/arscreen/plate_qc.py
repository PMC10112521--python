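"""Robust Z'-factor plate quality control.

The robust Z' factor summarizes, from raw signals, how well a plate
separates its positive-control wells from its vehicle wells:

    rZ' = 1 - 3 * (pmad + dmad) / |pmed - dmed|

where pmed/pmad are the median and scaled MAD of the MEC positive-control
signals and dmed/dmad those of the vehicle (DMSO) signals.  rZ' <= 1 always,
equals 1 only for zero variability, and values above 0.5 are conventionally
taken as HTS-suitable.  For ranking transiently transfected reporter pairs,
per-concentration rZ' values are summed into a cumulative rZ'.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assay_data import WellRecord, _mec_wells
from .normalization import mad

__all__ = [
    "PlateQCResult",
    "robust_zprime",
    "robust_zprime_from_signals",
    "cumulative_zprime",
    "median_plate_zprime",
]


@dataclass(frozen=True)
class PlateQCResult:
    plate_id: str
    pmed: float
    pmad: float
    dmed: float
    dmad: float
    rz_prime: float


def robust_zprime_from_signals(
    positive: Sequence[float],
    vehicle: Sequence[float],
    plate_id: str = "",
    mad_constant: float = 1.4826,
) -> PlateQCResult:
    """rZ' from raw positive-control and vehicle signal vectors.

    Accepts any >= 2 wells per group.  A zero median separation makes rZ'
    undefined; a ``-inf`` sentinel is returned with a warning.
    """
    if len(positive) < 2 or len(vehicle) < 2:
        raise ValueError("rZ' requires >= 2 positive and >= 2 vehicle wells")
    pmed = float(np.median(positive))
    dmed = float(np.median(vehicle))
    pmad = mad(positive, mad_constant)
    dmad = mad(vehicle, mad_constant)
    if pmed == dmed:
        warnings.warn(
            f"plate {plate_id or '<unnamed>'}: positive and vehicle medians "
            "coincide; rZ' undefined",
            stacklevel=2,
        )
        rz = -math.inf
    else:
        rz = 1.0 - 3.0 * (pmad + dmad) / abs(pmed - dmed)
    return PlateQCResult(
        plate_id=plate_id, pmed=pmed, pmad=pmad, dmed=dmed, dmad=dmad, rz_prime=rz
    )


def robust_zprime(
    plate_wells: Sequence[WellRecord], mad_constant: float = 1.4826
) -> PlateQCResult:
    """rZ' of one plate, computed on raw signals.

    Positive wells are the MEC wells of the plate's anchor control role
    (positive control for agonist/antagonist plates, cytotox control for
    the viability read).
    """
    if not plate_wells:
        raise ValueError("empty plate")
    plate_id = plate_wells[0].plate_id
    mode = plate_wells[0].mode
    anchor_role = "cytotox_control" if mode == "viability" else "positive_control"
    pos = [w.raw_signal for w in _mec_wells(plate_wells, anchor_role)]
    veh = [w.raw_signal for w in plate_wells if w.role == "vehicle"]
    return robust_zprime_from_signals(pos, veh, plate_id=plate_id,
                                      mad_constant=mad_constant)


def cumulative_zprime(rz_values: Sequence[float]) -> float:
    """Sum of per-concentration rZ' values (reporter-pair ranking metric)."""
    if len(rz_values) == 0:
        raise ValueError("cumulative rZ' of an empty list is undefined")
    return float(np.sum(rz_values))


def median_plate_zprime(results: Sequence[PlateQCResult]) -> float:
    """Campaign-level summary: the median of per-plate rZ' values."""
    if not results:
        raise ValueError("no plates")
    return float(np.median([r.rz_prime for r in results]))
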