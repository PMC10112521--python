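"""Scoring against reference chemicals and cross-assay potency comparison.

Packaged fixtures carry the per-chemical reference classes (strong /
moderate / weak / inactive) and the binary calls of four assay variants for
both agonist and antagonist modes.  Scoring binarizes the reference class
(strong, moderate and weak count as active), builds the confusion matrix
over chemicals tested in the scored assay, and reports sensitivity,
specificity and balanced accuracy.  Reported percentages are computed from
the unrounded fractions and rounded half-away-from-zero to whole percent
(62.5 -> 63, 93.75 -> 94).

For comparing potencies across assays without separate modes, each
chemical's combined potency is the minimum log10 AC50 over the modes in
which it is active; chemicals inactive in both modes receive a placeholder
of 2.5 log10 µM, which pins them to the inactive margin of a potency
scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assay_data import ReferenceChemical

__all__ = [
    "INACTIVE_PLACEHOLDER_LOG10_AC50",
    "ConfusionSummary",
    "binarize_reference",
    "confusion_matrix",
    "load_reference_table",
    "score_reference_table",
    "combined_log10_ac50",
    "assay_potency_table",
    "round_half_away",
]

INACTIVE_PLACEHOLDER_LOG10_AC50 = 2.5

_FIXTURES = {
    "agonist": "reference_agonists.csv",
    "antagonist": "reference_antagonists.csv",
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (62.5 -> 63)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and unrounded percentage metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy_pct(self) -> float:
        return (self.sensitivity_pct + self.specificity_pct) / 2.0

    def printed(self) -> dict[str, int]:
        """Whole-percent report, rounded half-away-from-zero."""
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity_pct": round_half_away(self.sensitivity_pct),
            "specificity_pct": round_half_away(self.specificity_pct),
            "balanced_accuracy_pct": round_half_away(self.balanced_accuracy_pct),
        }


def binarize_reference(ref: ReferenceChemical) -> bool | None:
    """Map a reference class to a truth label; ``None`` means excluded."""
    cls = ref.reference_class
    if cls in ("strong", "moderate", "weak"):
        return True
    if cls == "inactive":
        return False
    if cls == "not_tested":
        return None
    raise ValueError(f"unknown reference class {cls!r}")


def confusion_matrix(
    calls: Mapping[str, bool], refs: Iterable[ReferenceChemical]
) -> ConfusionSummary:
    """Score binary calls against reference truth labels.

    Excluded (not_tested) references are skipped; every remaining reference
    must have a call or a ``KeyError`` naming the chemical is raised.
    """
    tp = fp = fn = tn = 0
    for ref in refs:
        truth = binarize_reference(ref)
        if truth is None:
            continue
        if ref.chemical_id not in calls:
            raise KeyError(f"no call for tested reference {ref.chemical_id!r}")
        call = bool(calls[ref.chemical_id])
        if truth and call:
            tp += 1
        elif truth and not call:
            fn += 1
        elif not truth and call:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def load_reference_table(mode: str) -> pd.DataFrame:
    """Load the packaged reference truth table for one assay mode.

    Columns: ``chemical``, ``reference_class``, then one call column per
    assay variant with values "1"/"0"/"NT".
    """
    if mode not in _FIXTURES:
        raise ValueError(f"mode must be one of {sorted(_FIXTURES)}")
    with resources.files("arscreen.data").joinpath(_FIXTURES[mode]).open() as fh:
        return pd.read_csv(fh, dtype=str)


def score_reference_table(table: pd.DataFrame, assay_column: str,
                          mode: str = "agonist") -> ConfusionSummary:
    """Confusion summary for one assay column of a reference table.

    Chemicals marked "NT" (not tested) in that column are excluded.
    """
    if assay_column not in table.columns:
        raise KeyError(f"no column {assay_column!r} in table")
    refs, calls = [], {}
    for row in table.itertuples(index=False):
        chem = getattr(row, "chemical")
        raw_call = str(getattr(row, assay_column))
        cls = "not_tested" if raw_call == "NT" else str(row.reference_class)
        refs.append(ReferenceChemical(chemical_id=chem, mode=mode,
                                      reference_class=cls))
        if raw_call != "NT":
            calls[chem] = raw_call == "1"
    return confusion_matrix(calls, refs)


def combined_log10_ac50(
    ac50s_uM: Mapping[str, float | None],
    placeholder_log10_ac50: float = INACTIVE_PLACEHOLDER_LOG10_AC50,
) -> float:
    """Combined-mode potency: min log10 AC50 over active modes.

    ``ac50s_uM`` maps mode -> AC50 in µM (``None`` for inactive).  A
    chemical inactive in every mode gets the placeholder.
    """
    active = [v for v in ac50s_uM.values() if v is not None]
    if not active:
        return placeholder_log10_ac50
    return float(min(math.log10(v) for v in active))


def assay_potency_table(
    calls_by_assay: Mapping[str, Mapping[str, Mapping[str, float | None]]],
    placeholder_log10_ac50: float = INACTIVE_PLACEHOLDER_LOG10_AC50,
) -> pd.DataFrame:
    """Paired potency records for scatter comparison of two assays.

    ``calls_by_assay`` maps assay name -> chemical -> (mode -> AC50 µM or
    None).  Exactly two assays are compared over their common chemicals.
    The output has one row per chemical with each assay's combined log10
    AC50 and their difference; the median difference is a summary of which
    assay is generally more potent.
    """
    if len(calls_by_assay) != 2:
        raise ValueError("exactly two assays are compared")
    (name_a, a), (name_b, b) = calls_by_assay.items()
    common = sorted(set(a) & set(b))
    rows = []
    for chem in common:
        pa = combined_log10_ac50(a[chem], placeholder_log10_ac50)
        pb = combined_log10_ac50(b[chem], placeholder_log10_ac50)
        rows.append(
            {
                "chemical": chem,
                f"log10_ac50_{name_a}": pa,
                f"log10_ac50_{name_b}": pb,
                "diff_log10": pa - pb,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["median_diff_log10"] = (
        float(np.median(df["diff_log10"])) if len(df) else float("nan")
    )
    return df
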