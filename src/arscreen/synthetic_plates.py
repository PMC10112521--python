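"""Synthetic 384-well screening campaigns with known ground truth.

The generator inverts the analysis pipeline: each chemical carries Hill
ground truths for agonist activation (log2 fold units), antagonist
inhibition (% of the positive-control window) and cytotoxicity (% viability
loss), plus per-CYP phenomenological modifiers.  From those it forward
simulates raw plate-reader signals:

* agonist RLU  = baseline * 2^hill(conc) * noise
* antagonist RLU = [S - (S - floor) * inh(conc)/100] * (1 - v(conc)/100) * noise,
  where S is the agonist-stimulated signal (baseline * positive_fold),
  floor the unstimulated baseline, and v the viability loss — so a
  cytotoxic chemical suppresses the antagonist read at the same
  concentrations at which it kills cells (the loss-of-signal confound the
  gating rule exists to catch)
* viability RFU = [H - (H - D) * v(conc)/100] * noise for healthy signal H
  and dead-well floor D; the viability read shares its plate id (and well
  labels) with the antagonist plate it re-reads.

Noise is multiplicative lognormal with median 1 and a log-sd chosen so the
coefficient of variation equals ``noise_cv``; plate medians are therefore
unbiased, and ``noise_cv = 0`` reproduces the noiseless model exactly.
Each plate holds 8 DMSO wells, a 12-point positive-control titration with
4 replicate wells at the maximally effective concentration (MEC), a
12-point cytotox-control titration (antagonist plates only, likewise 4 MEC
wells), and an 11-point titration per test chemical; chemicals overflowing
one plate spill onto further plates.

A CYP modifier ``(potency_multiplier, efficacy_multiplier)`` maps the base
truth to AC50/potency_multiplier and top*efficacy_multiplier in that
biogroup, so a multiplier of 8 emulates a metabolite ~0.9 log10 units more
potent than the parent.  Modifiers apply to the agonist and antagonist
truths; cytotoxicity is left unmodified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .assay_data import Experiment, WellRecord
from .hill_fitting import hill_response

__all__ = [
    "HillTruth",
    "ChemicalTruth",
    "SimConfig",
    "simulate_experiment",
    "sample_truths",
    "test_concentrations",
]

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"
_PLATE_SIZE = 384


@dataclass(frozen=True)
class HillTruth:
    """Forward-model Hill parameters (bottom 0)."""

    top: float
    log10_ac50: float
    slope: float

    def __post_init__(self) -> None:
        if not self.top > 0:
            raise ValueError("top must be > 0")
        if not 0.3 <= self.slope <= 8:
            raise ValueError("slope must lie in [0.3, 8]")

    def __call__(self, conc_uM: float) -> float:
        return float(hill_response(conc_uM, self.top, self.log10_ac50, self.slope))

    def shifted(self, potency_multiplier: float, efficacy_multiplier: float) -> "HillTruth":
        return HillTruth(
            top=self.top * efficacy_multiplier,
            log10_ac50=self.log10_ac50 - math.log10(potency_multiplier),
            slope=self.slope,
        )


@dataclass(frozen=True)
class ChemicalTruth:
    """Ground truth for one chemical; ``None`` marks inactivity."""

    chemical_id: str
    agonist_params: HillTruth | None = None
    antagonist_params: HillTruth | None = None
    cytotox_params: HillTruth | None = None
    #: biogroup -> (potency_multiplier > 0, efficacy_multiplier in [0, 1]);
    #: AC50_biogroup = AC50_base / potency_multiplier (> 1 = bioactivation)
    cyp_modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bg, (pm, em) in self.cyp_modifiers.items():
            if not pm > 0:
                raise ValueError(f"{self.chemical_id}/{bg}: potency multiplier <= 0")
            if not 0 <= em <= 1:
                raise ValueError(
                    f"{self.chemical_id}/{bg}: efficacy multiplier outside [0, 1]"
                )

    def params_for(self, endpoint: str, biogroup: str) -> HillTruth | None:
        base = {
            "agonist": self.agonist_params,
            "antagonist": self.antagonist_params,
            "cytotox": self.cytotox_params,
        }[endpoint]
        if base is None or endpoint == "cytotox":
            return base
        if biogroup in self.cyp_modifiers:
            pm, em = self.cyp_modifiers[biogroup]
            if em == 0:
                return None
            return base.shifted(pm, em)
        return base


@dataclass
class SimConfig:
    """Study conditions for one simulated campaign."""

    n_test_chemicals: int = 10
    n_replicate_experiments: int = 3
    conc_points: int = 11
    conc_top_uM: float = 99.9
    dilution_factor: float = 3.162
    noise_cv: float = 0.10
    baseline_rlu: float = 1e4
    positive_fold: float = 75.0
    healthy_rfu: float = 5e4
    dead_rfu_fraction: float = 0.05
    seed: int = 0
    modes: tuple = ("agonist", "antagonist")
    biogroups: tuple = ("mock",)

    def __post_init__(self) -> None:
        positive = {
            "n_test_chemicals": self.n_test_chemicals,
            "n_replicate_experiments": self.n_replicate_experiments,
            "conc_points": self.conc_points,
            "conc_top_uM": self.conc_top_uM,
            "baseline_rlu": self.baseline_rlu,
            "positive_fold": self.positive_fold,
            "healthy_rfu": self.healthy_rfu,
            "dead_rfu_fraction": self.dead_rfu_fraction,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for m in self.modes:
            if m not in ("agonist", "antagonist"):
                raise ValueError(f"unknown simulation mode {m!r}")


def test_concentrations(cfg: SimConfig) -> np.ndarray:
    """Ascending test-chemical titration (µM), half-log by default."""
    steps = np.arange(cfg.conc_points - 1, -1, -1, dtype=float)
    return cfg.conc_top_uM / cfg.dilution_factor**steps


def _control_concentrations(top_uM: float, bottom_uM: float, n: int = 12) -> np.ndarray:
    factor = (top_uM / bottom_uM) ** (1.0 / (n - 1))
    return bottom_uM * factor ** np.arange(n)


# positive/cytotox control truths, in the simulator's normalized units
def _pc_agonist(cfg: SimConfig) -> HillTruth:
    return HillTruth(top=math.log2(cfg.positive_fold), log10_ac50=math.log10(5.6e-4),
                     slope=1.2)


_PC_ANTAGONIST = HillTruth(top=100.0, log10_ac50=math.log10(0.56), slope=1.2)
_CYTOTOX_CONTROL = HillTruth(top=100.0, log10_ac50=math.log10(5.0), slope=3.0)


class _WellLabels:
    def __init__(self) -> None:
        self._i = 0

    def next(self) -> str:
        if self._i >= _PLATE_SIZE:
            raise RuntimeError("plate overflow")
        row, col = divmod(self._i, 24)
        self._i += 1
        return f"{_PLATE_ROWS[row]}{col + 1:02d}"


def _noise(rng: np.random.Generator, cv: float) -> float:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.exp(rng.normal(0.0, sigma))


def _chunk(items: list, size: int) -> list[list]:
    return [items[i : i + size] for i in range(0, len(items), size)]


def simulate_experiment(
    truths: list[ChemicalTruth], cfg: SimConfig
) -> tuple[Experiment, dict]:
    """Simulate a campaign; returns the Experiment and its truth record.

    Identical config (including seed) gives identical output.  The truth
    record carries the config and, per chemical and biogroup, the effective
    Hill parameters for each endpoint.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    seen = set()
    for t in truths:
        if t.chemical_id in seen:
            raise ValueError(f"duplicate chemical id {t.chemical_id!r}")
        seen.add(t.chemical_id)

    rng = np.random.default_rng(cfg.seed)
    concs = test_concentrations(cfg)
    pc_ag = _pc_agonist(cfg)
    pc_ag_concs = _control_concentrations(0.01, 7.22e-4)
    ctrl_concs = _control_concentrations(99.8, 0.722)

    wells: list[WellRecord] = []

    def emit(plate_id, labels, role, chem, conc, mode, biogroup, signal) -> None:
        wells.append(
            WellRecord(
                plate_id=plate_id,
                well=labels.next(),
                role=role,
                chemical_id=chem,
                conc_uM=float(conc),
                mode=mode,
                biogroup=biogroup,
                raw_signal=float(signal),
            )
        )

    n_ctrl_wells = {
        # 8 DMSO + PC titration (11 singles + 4 MEC); antagonist adds dichlone-like
        "agonist": 8 + (len(pc_ag_concs) - 1) + 4,
        "antagonist": 8 + (len(ctrl_concs) - 1) + 4 + (len(ctrl_concs) - 1) + 4,
    }

    stim = cfg.baseline_rlu * cfg.positive_fold
    floor = cfg.baseline_rlu
    healthy = cfg.healthy_rfu
    dead = cfg.healthy_rfu * cfg.dead_rfu_fraction

    def ag_rlu(resp_log2: float) -> float:
        return cfg.baseline_rlu * 2.0**resp_log2 * _noise(rng, cfg.noise_cv)

    def ant_rlu(inh_pct: float, viab_loss_pct: float) -> float:
        signal = stim - (stim - floor) * inh_pct / 100.0
        return signal * (1.0 - viab_loss_pct / 100.0) * _noise(rng, cfg.noise_cv)

    def via_rfu(viab_loss_pct: float) -> float:
        return (healthy - (healthy - dead) * viab_loss_pct / 100.0) * _noise(
            rng, cfg.noise_cv
        )

    for rep in range(1, cfg.n_replicate_experiments + 1):
        for biogroup in cfg.biogroups:
            for mode in cfg.modes:
                capacity = (_PLATE_SIZE - n_ctrl_wells[mode]) // cfg.conc_points
                for p, batch in enumerate(_chunk(truths, capacity), start=1):
                    plate_id = f"E{rep}-{mode[:3]}-{biogroup}-P{p:02d}"
                    labels = _WellLabels()
                    via_rows: list[tuple[str, str, str, float, float]] = []

                    for _ in range(8):  # vehicle
                        if mode == "agonist":
                            sig = ag_rlu(0.0)
                        else:
                            sig = ant_rlu(0.0, 0.0)
                        emit(plate_id, labels, "vehicle", "", 0.0, mode, biogroup, sig)
                        if mode == "antagonist":
                            via_rows.append(("vehicle", "", 0.0, 0.0, 0.0))

                    pc_concs = pc_ag_concs if mode == "agonist" else ctrl_concs
                    pc_list = list(pc_concs[:-1]) + [pc_concs[-1]] * 4
                    for c in pc_list:
                        if mode == "agonist":
                            sig = ag_rlu(pc_ag(c))
                        else:
                            sig = ant_rlu(_PC_ANTAGONIST(c), 0.0)
                        emit(plate_id, labels, "positive_control",
                             "positive_control", c, mode, biogroup, sig)
                        if mode == "antagonist":
                            via_rows.append(
                                ("positive_control", "positive_control", c, 0.0, 0.0)
                            )

                    if mode == "antagonist":
                        for c in list(ctrl_concs[:-1]) + [ctrl_concs[-1]] * 4:
                            v = _CYTOTOX_CONTROL(c)
                            emit(plate_id, labels, "cytotox_control",
                                 "cytotox_control", c, mode, biogroup,
                                 ant_rlu(0.0, v))
                            via_rows.append(
                                ("cytotox_control", "cytotox_control", c, 0.0, v)
                            )

                    for truth in batch:
                        for c in concs:
                            if mode == "agonist":
                                p_ag = truth.params_for("agonist", biogroup)
                                sig = ag_rlu(p_ag(c) if p_ag else 0.0)
                            else:
                                p_ant = truth.params_for("antagonist", biogroup)
                                p_cyt = truth.params_for("cytotox", biogroup)
                                inh = p_ant(c) if p_ant else 0.0
                                v = p_cyt(c) if p_cyt else 0.0
                                sig = ant_rlu(inh, v)
                            emit(plate_id, labels, "test", truth.chemical_id,
                                 c, mode, biogroup, sig)
                            if mode == "antagonist":
                                p_cyt = truth.params_for("cytotox", biogroup)
                                via_rows.append(
                                    ("test", truth.chemical_id, c, 0.0,
                                     p_cyt(c) if p_cyt else 0.0)
                                )

                    if mode == "antagonist":
                        # post-hoc viability read of the same physical plate
                        via_labels = _WellLabels()
                        for role, chem, c, _inh, v in via_rows:
                            emit(plate_id, via_labels, role, chem, c,
                                 "viability", biogroup, via_rfu(v))

    truth_record = {
        "config": asdict(cfg),
        "chemicals": {
            t.chemical_id: {
                bg: {
                    endpoint: (None if p is None else asdict(p))
                    for endpoint, p in (
                        ("agonist", t.params_for("agonist", bg)),
                        ("antagonist", t.params_for("antagonist", bg)),
                        ("cytotox", t.params_for("cytotox", bg)),
                    )
                }
                for bg in cfg.biogroups
            }
            for t in truths
        },
    }
    exp = Experiment(wells=wells, metadata={"simulated": True, "seed": cfg.seed})
    return exp, truth_record


#: deterministic category cycle used by sample_truths
_CATEGORIES = (
    "agonist", "agonist", "agonist", "agonist",
    "antagonist", "antagonist", "antagonist",
    "antagonist_cytotox", "cytotox_only", "inactive",
)


def sample_truths(
    n: int,
    seed: int,
    cyp_modifiers: dict | None = None,
) -> list[ChemicalTruth]:
    """Draw a mixed panel of ground-truth chemicals.

    Categories cycle deterministically (40% agonists, 30% clean
    antagonists, 10% gated antagonist+cytotox, 10% cytotox-only, 10%
    inactive); potencies are drawn log-uniform well inside the tested
    range, agonist efficacies between 3 and 6.5 log2 fold, inhibition
    efficacies between 60 and 100%.  ``cyp_modifiers`` is applied to every
    active chemical.
    """
    rng = np.random.default_rng(seed)
    out: list[ChemicalTruth] = []
    for i in range(n):
        cat = _CATEGORIES[i % len(_CATEGORIES)]
        ac50 = float(rng.uniform(-1.5, 1.0))
        slope = float(rng.uniform(1.0, 3.0))
        ag = ant = cyt = None
        if cat == "agonist":
            ag = HillTruth(top=float(rng.uniform(3.0, 6.5)), log10_ac50=ac50,
                           slope=slope)
        elif cat == "antagonist":
            ant = HillTruth(top=float(rng.uniform(60.0, 100.0)),
                            log10_ac50=ac50, slope=slope)
        elif cat == "antagonist_cytotox":
            ant = HillTruth(top=float(rng.uniform(60.0, 100.0)),
                            log10_ac50=ac50, slope=slope)
            cyt = HillTruth(top=100.0,
                            log10_ac50=ac50 + float(rng.uniform(0.8, 1.4)),
                            slope=slope)
        elif cat == "cytotox_only":
            cyt = HillTruth(top=100.0, log10_ac50=ac50, slope=slope)
        mods = dict(cyp_modifiers) if (cyp_modifiers and cat != "inactive") else {}
        out.append(
            ChemicalTruth(
                chemical_id=f"chem{i:03d}",
                agonist_params=ag,
                antagonist_params=ant,
                cytotox_params=cyt,
                cyp_modifiers=mods,
            )
        )
    return out
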