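"""Hit calling: bmad-multiple thresholds plus cytotoxicity gating.

An agonist is active when its maximal per-concentration median response
exceeds 5 x bmad.  An antagonist must exceed 3 x bmad AND, if the chemical
is itself cytotoxic (its viability series is a 3 x bmad hit), have an
antagonist AC50 at least 0.5 log10 units (3.16-fold) below its cytotoxicity
AC50 — otherwise the apparent inhibition is a loss-of-signal artifact of
dying cells and the call is recorded as confounded.  Threshold comparisons
are strict (">"); the log-separation test is ">= 0.5".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .assay_data import ExperimentThresholds
from .hill_fitting import HillFit, max_median_response
from .normalization import ConcentrationSeries

__all__ = [
    "AGONIST_BMAD_MULT",
    "ANTAGONIST_BMAD_MULT",
    "CYTOTOX_LOG10_SEPARATION",
    "ActivityCall",
    "call_agonist",
    "call_antagonist",
]

AGONIST_BMAD_MULT = 5.0
ANTAGONIST_BMAD_MULT = 3.0
CYTOTOX_LOG10_SEPARATION = 0.5

GATING_VALUES = (
    "not_applicable",
    "passed",
    "confounded_by_cytotoxicity",
    "not_cytotoxic",
)


@dataclass(frozen=True)
class ActivityCall:
    """Active/inactive verdict with the evidence that produced it.

    ``threshold`` is the bmad multiple the maximal median was compared to;
    ``gating`` records the cytotoxicity decision for antagonist calls.
    Inactive (and confounded) calls carry no AC50.
    """

    chemical_id: str
    mode: str
    biogroup: str
    active: bool
    max_median_resp: float
    max_median_conc_uM: float
    threshold: float
    bmad: float
    ac50_uM: float | None = None
    cytotox_ac50_uM: float | None = None
    gating: str = "not_applicable"
    comment: str = ""


def call_agonist(
    series: ConcentrationSeries,
    fit: HillFit,
    thresholds: ExperimentThresholds,
    bmad_mult: float = AGONIST_BMAD_MULT,
) -> ActivityCall:
    """Agonist hit call: maximal median response > 5 x bmad."""
    bmad = thresholds.bmad_agonist
    if bmad <= 0:
        raise ValueError(
            "agonist bmad is 0; check vehicle-well QC before calling hits"
        )
    conc, max_med = max_median_response(series)
    threshold = bmad_mult * bmad
    active = max_med > threshold
    return ActivityCall(
        chemical_id=series.chemical_id,
        mode=series.mode,
        biogroup=series.biogroup,
        active=active,
        max_median_resp=max_med,
        max_median_conc_uM=conc,
        threshold=threshold,
        bmad=bmad,
        ac50_uM=fit.ac50_uM if active else None,
    )


def call_antagonist(
    series: ConcentrationSeries,
    fit: HillFit,
    viability_series: ConcentrationSeries | None,
    viability_fit: HillFit | None,
    thresholds: ExperimentThresholds,
    bmad_mult: float = ANTAGONIST_BMAD_MULT,
    log10_separation: float = CYTOTOX_LOG10_SEPARATION,
) -> ActivityCall:
    """Antagonist hit call with cytotoxicity gating.

    The chemical is a candidate when its maximal median inhibition exceeds
    3 x bmad.  Candidates are gated: if the matched viability series is
    itself a 3 x bmad hit, the antagonist AC50 must sit at least 0.5 log10
    units below the cytotoxicity AC50 or the call is confounded.  A
    candidate whose antagonist fit did not converge is deferred (inactive
    with a diagnostic comment and warning).
    """
    bmad = thresholds.bmad_antagonist
    if bmad <= 0:
        raise ValueError(
            "antagonist bmad is 0; check vehicle-well QC before calling hits"
        )
    conc, max_med = max_median_response(series)
    threshold = bmad_mult * bmad
    common = dict(
        chemical_id=series.chemical_id,
        mode=series.mode,
        biogroup=series.biogroup,
        max_median_resp=max_med,
        max_median_conc_uM=conc,
        threshold=threshold,
        bmad=bmad,
    )
    if not max_med > threshold:
        return ActivityCall(active=False, **common)
    if not fit.converged:
        warnings.warn(
            f"{series.chemical_id} [{series.biogroup}]: antagonist fit did "
            "not converge; call deferred",
            stacklevel=2,
        )
        return ActivityCall(
            active=False,
            comment="deferred: antagonist fit did not converge",
            **common,
        )

    cytotoxic = False
    cytotox_ac50 = None
    if viability_series is not None and viability_series.points:
        viab_bmad = thresholds.bmad_for("viability")
        if viab_bmad <= 0:
            raise ValueError(
                "viability bmad is 0; check vehicle-well QC before gating"
            )
        _, viab_max = max_median_response(viability_series)
        if viab_max > bmad_mult * viab_bmad:
            cytotoxic = True
            if viability_fit is None:
                raise ValueError(
                    f"{series.chemical_id}: cytotoxic but no viability fit "
                    "supplied for gating"
                )
            cytotox_ac50 = viability_fit.ac50_uM

    if not cytotoxic:
        return ActivityCall(
            active=True,
            ac50_uM=fit.ac50_uM,
            gating="not_cytotoxic",
            **common,
        )
    delta = math.log10(cytotox_ac50) - fit.log10_ac50
    if delta >= log10_separation:
        return ActivityCall(
            active=True,
            ac50_uM=fit.ac50_uM,
            cytotox_ac50_uM=cytotox_ac50,
            gating="passed",
            **common,
        )
    return ActivityCall(
        active=False,
        cytotox_ac50_uM=cytotox_ac50,
        gating="confounded_by_cytotoxicity",
        comment=f"antagonist/cytotox AC50 separation {delta:.3f} log10 < "
        f"{log10_separation}",
        **common,
    )
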