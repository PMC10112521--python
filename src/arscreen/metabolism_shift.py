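"""Cross-biogroup comparison: CYP-dependent activity and potency shifts.

Each chemical is screened under twelve transfection biogroups: mock (no
RNA), beta-galactosidase (Bgal, a non-specific control), and ten human CYP
enzymes.  Comparing a CYP biogroup's call and AC50 against the metabolically
naive reference condition flags apparent bioactivation (a gained call or a
potency increase — a more potent metabolite is formed) and apparent
inactivation (a lost call or potency reduction — the parent is cleared).

The reference potency is the median log10 AC50 across all biogroups in
which the chemical is active when a majority of biogroups are active,
otherwise the active members of the mock/Bgal pair.  fold_shift =
reference AC50 / biogroup AC50, so values > 1 mean the biogroup is more
potent (bioactivation direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .activity_calls import ActivityCall

__all__ = [
    "DEFAULT_FOLD_CUTOFF",
    "MIN_DELTA_LOG10",
    "CypShiftResult",
    "potency_shift",
    "classify_shift",
]

DEFAULT_FOLD_CUTOFF = 2.0
#: a fold shift must also clear this many log10 units to count
MIN_DELTA_LOG10 = 0.3

SHIFT_LABELS = (
    "bioactivated",
    "inactivated",
    "potency_reduced",
    "potency_increased",
    "unchanged",
)


@dataclass(frozen=True)
class CypShiftResult:
    chemical_id: str
    mode: str
    biogroup: str
    reference_ac50_uM: float | None
    fold_shift: float | None
    call_change: str  # none | gained_activity | lost_activity
    shift_label: str
    marginal: bool = False

    def __post_init__(self) -> None:
        if self.fold_shift is not None and not self.fold_shift > 0:
            raise ValueError("fold_shift must be > 0")


def _consensus_active(calls: dict[str, ActivityCall]) -> bool:
    """Mock/Bgal consensus: both agree -> that; split -> mock decides."""
    mock, bgal = calls["mock"].active, calls["bgal"].active
    return mock if mock != bgal else mock


def _reference_ac50(calls: dict[str, ActivityCall]) -> float | None:
    active_ac50s = [
        c.ac50_uM for c in calls.values() if c.active and c.ac50_uM is not None
    ]
    if len(active_ac50s) * 2 > len(calls):
        # majority of biogroups active: median across the active biogroups
        return float(10 ** np.median(np.log10(active_ac50s)))
    ref = [
        calls[g].ac50_uM
        for g in ("mock", "bgal")
        if calls[g].active and calls[g].ac50_uM is not None
    ]
    if ref:
        return float(10 ** np.median(np.log10(ref)))
    return None


def _is_marginal(call: ActivityCall) -> bool:
    """Within one bmad of the activity threshold on either side."""
    return abs(call.max_median_resp - call.threshold) < call.bmad


def potency_shift(calls: list[ActivityCall] | dict[str, ActivityCall]) -> list[CypShiftResult]:
    """Per-biogroup shift results for one chemical and mode.

    Requires the mock and bgal reference conditions.  Calls that sit within
    one bmad of the threshold are annotated marginal — a gained or lost call
    there is weak evidence.
    """
    if isinstance(calls, list):
        calls = {c.biogroup: c for c in calls}
    if not calls:
        raise ValueError("no calls")
    some = next(iter(calls.values()))
    if any(c.chemical_id != some.chemical_id or c.mode != some.mode
           for c in calls.values()):
        raise ValueError("calls must share one chemical and mode")
    for required in ("mock", "bgal"):
        if required not in calls:
            raise ValueError(f"reference biogroup {required!r} missing")

    consensus = _consensus_active(calls)
    ref_ac50 = _reference_ac50(calls)

    out: list[CypShiftResult] = []
    for biogroup, call in calls.items():
        if call.active and not consensus:
            change = "gained_activity"
        elif not call.active and consensus:
            change = "lost_activity"
        else:
            change = "none"
        fold = None
        if call.active and call.ac50_uM is not None and ref_ac50 is not None:
            fold = ref_ac50 / call.ac50_uM
        result = CypShiftResult(
            chemical_id=call.chemical_id,
            mode=call.mode,
            biogroup=biogroup,
            reference_ac50_uM=ref_ac50,
            fold_shift=fold,
            call_change=change,
            shift_label="unchanged",
            marginal=_is_marginal(call) and change != "none",
        )
        out.append(replace(result, shift_label=classify_shift(result)))
    return out


def classify_shift(
    result: CypShiftResult,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
    min_delta_log10: float = MIN_DELTA_LOG10,
) -> str:
    """Label a shift result.

    Gained and lost calls dominate; otherwise a fold shift beyond the cutoff
    (and beyond ``min_delta_log10`` in magnitude) labels the biogroup as
    potency_increased / potency_reduced, else unchanged.
    """
    if result.call_change == "gained_activity":
        return "bioactivated"
    if result.call_change == "lost_activity":
        return "inactivated"
    if result.fold_shift is not None:
        delta = abs(math.log10(result.fold_shift))
        if result.fold_shift >= fold_cutoff and delta >= min_delta_log10:
            return "potency_increased"
        if result.fold_shift <= 1.0 / fold_cutoff and delta >= min_delta_log10:
            return "potency_reduced"
    return "unchanged"
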