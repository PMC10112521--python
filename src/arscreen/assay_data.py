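"""Domain types and CSV IO for well-level plate-reader data.

The atom of the pipeline is a :class:`WellRecord`: one well's raw signal
(RLU for luminescent reads, RFU for the resazurin viability read) together
with its full treatment annotation.  An :class:`Experiment` is a flat
collection of wells, possibly spanning many plates, assay modes and
transfection biogroups; the grouping key for all plate-level computation is
``(plate_id, mode, biogroup)``.

Concentrations are stored in micromolar throughout; every log-potency
quantity downstream is log10(µM).  Well positions ("A01") are metadata only
and are never interpreted geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ROLES",
    "MODES",
    "BIOGROUPS",
    "WELL_COLUMNS",
    "WellRecord",
    "Experiment",
    "ReferenceChemical",
    "ExperimentThresholds",
    "SchemaError",
    "ValidationError",
    "read_well_table",
    "write_well_table",
    "validate_experiment",
]

ROLES = ("vehicle", "positive_control", "cytotox_control", "test")
MODES = ("agonist", "antagonist", "viability")
BIOGROUPS = (
    "mock",
    "bgal",
    "CYP1A2",
    "CYP2A6",
    "CYP2B6",
    "CYP2C8",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP2E1",
    "CYP2J2",
    "CYP3A4",
)

#: exact input/output CSV schema, in column order
WELL_COLUMNS = (
    "plate_id",
    "well",
    "role",
    "chemical_id",
    "conc_uM",
    "mode",
    "biogroup",
    "raw_signal",
)

#: minimum plate-design requirements (vehicle replicates and MEC
#: positive-control replicates per plate)
MIN_VEHICLE_WELLS = 8
MIN_MEC_WELLS = 4


class SchemaError(ValueError):
    """Input table does not match the expected column schema."""


class ValidationError(ValueError):
    """A well record violates a hard invariant (e.g. negative signal)."""


@dataclass(frozen=True)
class WellRecord:
    """One well: treatment annotation plus its raw plate-reader signal."""

    plate_id: str
    well: str
    role: str
    chemical_id: str
    conc_uM: float
    mode: str
    biogroup: str
    raw_signal: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} in well {self.well}")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r} in well {self.well}")
        if self.biogroup not in BIOGROUPS:
            raise ValidationError(
                f"unknown biogroup {self.biogroup!r} in well {self.well}"
            )
        if not self.raw_signal >= 0:
            raise ValidationError(
                f"raw_signal must be >= 0, got {self.raw_signal} in well "
                f"{self.plate_id}/{self.well}"
            )
        if not self.conc_uM >= 0:
            raise ValidationError(
                f"conc_uM must be >= 0, got {self.conc_uM} in well "
                f"{self.plate_id}/{self.well}"
            )
        if self.role == "vehicle" and self.conc_uM != 0:
            raise ValidationError(
                f"vehicle well {self.plate_id}/{self.well} must have conc_uM = 0"
            )


@dataclass
class Experiment:
    """A collection of wells from one screening campaign.

    ``replicate_id`` indexes independent biological experiments when a
    campaign is stored as several Experiment objects; the simulator instead
    encodes the replicate in the plate id and emits one Experiment.
    """

    wells: list[WellRecord]
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.wells)

    def to_frame(self) -> pd.DataFrame:
        """Well table as a DataFrame with the canonical column order."""
        return pd.DataFrame([asdict(w) for w in self.wells], columns=list(WELL_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate_id: int = 0) -> "Experiment":
        missing = [c for c in WELL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        wells = []
        for idx, row in enumerate(df.itertuples(index=False)):
            try:
                wells.append(
                    WellRecord(
                        plate_id=str(getattr(row, "plate_id")),
                        well=str(getattr(row, "well")),
                        role=str(getattr(row, "role")),
                        chemical_id=("" if pd.isna(getattr(row, "chemical_id"))
                                     else str(getattr(row, "chemical_id"))),
                        conc_uM=float(getattr(row, "conc_uM")),
                        mode=str(getattr(row, "mode")),
                        biogroup=str(getattr(row, "biogroup")),
                        raw_signal=float(getattr(row, "raw_signal")),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
        return cls(wells=wells, replicate_id=replicate_id)

    def plates(self) -> dict[tuple[str, str, str], list[WellRecord]]:
        """Group wells by the plate key ``(plate_id, mode, biogroup)``.

        Insertion order of first appearance is preserved.
        """
        groups: dict[tuple[str, str, str], list[WellRecord]] = {}
        for w in self.wells:
            groups.setdefault((w.plate_id, w.mode, w.biogroup), []).append(w)
        return groups


@dataclass(frozen=True)
class ReferenceChemical:
    """A chemical with an externally curated activity class.

    ``reference_class`` ``not_tested`` marks chemicals excluded from
    confusion-matrix scoring for a given assay.
    """

    chemical_id: str
    mode: str
    reference_class: str

    _CLASSES = ("strong", "moderate", "weak", "inactive", "not_tested")

    def __post_init__(self) -> None:
        if self.mode not in ("agonist", "antagonist"):
            raise ValidationError(f"reference mode must be agonist/antagonist")
        if self.reference_class not in self._CLASSES:
            raise ValidationError(
                f"unknown reference class {self.reference_class!r}"
            )


@dataclass
class ExperimentThresholds:
    """Experiment-wide baseline variability, one bmad per assay mode.

    bmad is the median absolute deviation (scaled by ``mad_constant``,
    default the Gaussian consistency constant 1.4826) of normalized vehicle
    responses across the entire experiment.  The agonist bmad is in log2
    fold-change units, the antagonist and viability bmads in % of positive
    control; they are never compared across modes.  ``bmad_viability``
    defaults to the antagonist value when no viability-plate vehicle wells
    are available.
    """

    bmad_agonist: float
    bmad_antagonist: float
    bmad_viability: float | None = None
    mad_constant: float = 1.4826

    def __post_init__(self) -> None:
        if self.bmad_agonist < 0 or self.bmad_antagonist < 0:
            raise ValidationError("bmad values must be >= 0")
        if self.bmad_viability is not None and self.bmad_viability < 0:
            raise ValidationError("bmad values must be >= 0")

    def bmad_for(self, mode: str) -> float:
        if mode == "agonist":
            return self.bmad_agonist
        if mode == "antagonist":
            return self.bmad_antagonist
        if mode == "viability":
            return (
                self.bmad_viability
                if self.bmad_viability is not None
                else self.bmad_antagonist
            )
        raise ValueError(f"unknown mode {mode!r}")


def read_well_table(path) -> Experiment:
    """Read a well-level CSV into a validated :class:`Experiment`.

    The header must contain exactly the :data:`WELL_COLUMNS` fields (extra
    columns are ignored); row order is preserved.  A missing column raises
    :class:`SchemaError` naming the column; an invalid value raises
    :class:`ValidationError` carrying the offending row index.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "chemical_id": str})
    return Experiment.from_frame(df)


def write_well_table(exp: Experiment, path) -> None:
    """Write an Experiment back to the canonical CSV schema."""
    exp.to_frame().to_csv(path, index=False)


def _mec_wells(wells: Iterable[WellRecord], role: str) -> list[WellRecord]:
    """Control wells at the maximal tested control concentration."""
    ctrl = [w for w in wells if w.role == role]
    if not ctrl:
        return []
    mec = max(w.conc_uM for w in ctrl)
    return [w for w in ctrl if w.conc_uM == mec]


def validate_experiment(exp: Experiment) -> list[str]:
    """Check plate-design invariants; violations are returned, not raised.

    Per plate key ``(plate_id, mode, biogroup)``: at least 8 vehicle wells;
    at least 4 replicate control wells at the maximally effective
    concentration (the positive control for agonist/antagonist plates, the
    cytotox control for viability plates); unique well labels.  Across
    modes, one physical plate id may carry an antagonist read and its
    post-hoc viability read, but never mixed agonist and antagonist wells.
    The result is order-insensitive (sorted).
    """
    violations: list[str] = []
    modes_per_plate: dict[str, set[str]] = {}
    for (plate_id, mode, biogroup), wells in exp.plates().items():
        key = f"plate {plate_id} [{mode}/{biogroup}]"
        modes_per_plate.setdefault(plate_id, set()).add(mode)
        n_veh = sum(1 for w in wells if w.role == "vehicle")
        if n_veh < MIN_VEHICLE_WELLS:
            violations.append(
                f"{key}: {n_veh} vehicle wells, need >= {MIN_VEHICLE_WELLS}"
            )
        anchor_role = "cytotox_control" if mode == "viability" else "positive_control"
        n_mec = len(_mec_wells(wells, anchor_role))
        if n_mec < MIN_MEC_WELLS:
            violations.append(
                f"{key}: {n_mec} {anchor_role} wells at MEC, need >= {MIN_MEC_WELLS}"
            )
        labels = [w.well for w in wells]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            violations.append(f"{key}: duplicate well label(s) {', '.join(dupes)}")
        groups = {w.biogroup for w in wells}
        if len(groups) > 1:  # unreachable through plates(); guards manual use
            violations.append(f"{key}: mixed biogroups {sorted(groups)}")
    for plate_id, modes in modes_per_plate.items():
        if "agonist" in modes and "antagonist" in modes:
            violations.append(
                f"plate {plate_id}: mixes agonist and antagonist wells "
                f"(mode homogeneity)"
            )
    return sorted(violations)
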