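"""Synthetic round-robin study generator with known ground truth.

Each simulated well's true induction factor is

    IF = 1 + (hill(c) - 1) * (viability(c)/100)**coupling * A
         + lab_effect + experiment_effect + well_noise,

where ``hill`` is the substance's true 4PL curve, the viability term folds a
logistic cytotoxic decline into the reporter response (reproducing the bell
shape of cytotoxic inducers without claiming mechanism), and ``A`` is a
lognormal response-amplitude factor per (laboratory, substance) and per
(experiment, substance). Additive lab/experiment/well effects are plain
Gaussians on the IF scale, matching the scale on which the assay's
precision is reported. Raw luminescence is IF times the plate's solvent
level; solvent wells are drawn around ``rlu_baseline`` with coefficient of
variation ``rlu_cv``, so the induction pipeline recovers the truth exactly
when every noise term is zero.

A single root seed drives a hierarchical ``numpy`` SeedSequence scheme
(study -> lab -> experiment -> plate), so any subset of the study is
reproducible independently of the rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .plate_model import (
    MOLAR,
    UG_PER_ML,
    DilutionSeries,
    PlateLayout,
    PlateRead,
    StudyDataset,
    WellRole,
    default_curcumin_series,
    default_dichlorvos_series,
    default_mannitol_series,
    make_log_dilution_series,
    standard_biorima_layout,
    viability_layout,
)


@dataclass(frozen=True)
class SubstanceTruth:
    """Ground-truth response of one substance.

    ``hill`` is (bottom, top, log10_ec50, hill_slope) of the true IF curve;
    ``cytotox`` is (viability_floor %, log10_lc50, slope) of the logistic
    viability decline, or None for a non-cytotoxic substance;
    ``cytotox_coupling`` in [0, 1] scales how strongly viability loss
    suppresses the observed reporter signal. ``amp_sigma_lab`` /
    ``amp_sigma_exp`` are lognormal sigmas of the response-amplitude factor.
    """

    substance: str
    series: DilutionSeries
    hill: tuple[float, float, float, float]
    cytotox: tuple[float, float, float] | None = None
    cytotox_coupling: float = 0.0
    amp_sigma_lab: float = 0.0
    amp_sigma_exp: float = 0.0

    def __post_init__(self) -> None:
        if self.hill[0] < 0:
            raise ValueError("hill bottom must be >= 0")
        if self.cytotox is not None and not 0 <= self.cytotox[0] <= 100:
            raise ValueError("viability floor must be in [0, 100]")
        if not 0 <= self.cytotox_coupling <= 1:
            raise ValueError("cytotox_coupling must be in [0, 1]")

    def hill_if(self, conc: float) -> float:
        bottom, top, log_ec50, slope = self.hill
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - math.log10(conc)) * slope))

    def viability_percent(self, conc: float) -> float:
        if self.cytotox is None:
            return 100.0
        floor, log_lc50, slope = self.cytotox
        return floor + (100.0 - floor) / (1.0 + 10.0 ** ((math.log10(conc) - log_lc50) * slope))

    def true_if(self, conc: float) -> float:
        """Noise-free observed IF: Hill response shrunk toward 1 by cytotoxicity."""
        supp = (self.viability_percent(conc) / 100.0) ** self.cytotox_coupling
        return 1.0 + (self.hill_if(conc) - 1.0) * supp


@dataclass
class StudyTruth:
    """Everything the generator needs to emit one round-robin study."""

    labs: int
    experiments_per_lab: int
    substances: list[SubstanceTruth]
    reference_truth: SubstanceTruth
    positive_control_truth: SubstanceTruth
    negative_control_truth: SubstanceTruth
    sigma_lab: float = 0.0
    sigma_exp: float = 0.0
    sigma_well: float = 0.0
    rlu_baseline: float = 20000.0
    rlu_cv: float = 0.0
    viability_baseline: float = 50000.0
    seed: int = 0
    lab_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labs < 2 or self.experiments_per_lab < 2:
            raise ValueError("need at least 2 labs and 2 experiments per lab")
        if min(self.sigma_lab, self.sigma_exp, self.sigma_well, self.rlu_cv) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.lab_ids:
            self.lab_ids = [f"LAB{i + 1}" for i in range(self.labs)]
        if len(self.lab_ids) != self.labs:
            raise ValueError("lab_ids length must equal labs")

    def all_truths(self) -> list[SubstanceTruth]:
        return [self.reference_truth, self.positive_control_truth,
                self.negative_control_truth, *self.substances]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyTruth":
        d = json.loads(text)

        def sub(s):
            s = dict(s)
            ser = s.pop("series")
            s["series"] = DilutionSeries(ser["substance"], tuple(ser["concentrations"]), ser["unit"])
            s["hill"] = tuple(s["hill"])
            if s.get("cytotox") is not None:
                s["cytotox"] = tuple(s["cytotox"])
            return SubstanceTruth(**s)

        d["substances"] = [sub(s) for s in d["substances"]]
        for key in ("reference_truth", "positive_control_truth", "negative_control_truth"):
            d[key] = sub(d[key])
        return cls(**d)


@dataclass
class SimulationResult:
    dataset: StudyDataset
    truth: StudyTruth
    n_clipped_wells: int
    true_if: dict[str, dict] = field(default_factory=dict)  # plate_id -> {coord: noise-free IF}


def _plate_signal(
    rng: np.random.Generator,
    layout: PlateLayout,
    truths: dict[str, SubstanceTruth],
    amp: dict[str, float],
    additive_offset: float,
    sigma_well: float,
    rlu_baseline: float,
    rlu_cv: float,
) -> tuple[dict, dict, int]:
    """Draw one luciferase plate; returns (signal, noise-free IF map, clipped count)."""
    signal: dict = {}
    true_if: dict = {}
    clipped = 0
    for coord in layout.usable_wells:
        a = layout.wells[coord]
        gain = 1.0 + rlu_cv * rng.standard_normal() if rlu_cv > 0 else 1.0
        if a.role is WellRole.SOLVENT_CONTROL:
            rlu = rlu_baseline * gain
            true_if[coord] = 1.0
        else:
            t = truths[a.substance]
            base = t.true_if(a.concentration)
            true_if[coord] = 1.0 + (base - 1.0) * amp.get(a.substance, 1.0)
            if_obs = true_if[coord] + additive_offset + sigma_well * rng.standard_normal()
            rlu = if_obs * rlu_baseline * gain
        if rlu < 0:
            rlu = 0.0
            clipped += 1
        signal[coord] = rlu
    return signal, true_if, clipped


def simulate_study(truth: StudyTruth, include_viability: bool = True,
                   keep_true_if: bool = False) -> SimulationResult:
    """Generate a full round-robin study (reference + experimental plates per
    lab and experiment, plus one lab's viability plates) from ``truth``.

    Deterministic given ``truth.seed``. Negative generated RLU values are
    clipped at 0 and counted in the result.
    """
    truths = {t.substance: t for t in truth.all_truths()}
    ref_layout = standard_biorima_layout(
        "reference",
        curcumin_series=truth.reference_truth.series,
        dichlorvos_series=truth.positive_control_truth.series,
        mannitol_series=truth.negative_control_truth.series,
    )
    exp_layouts = {
        t.substance: standard_biorima_layout(
            "experimental", t.substance, t.series, curcumin_series=truth.reference_truth.series
        )
        for t in truth.substances
    }

    root = np.random.SeedSequence(truth.seed)
    lab_seqs = root.spawn(truth.labs + 1)  # last one drives the viability lab
    plates: list[PlateRead] = []
    true_if_maps: dict[str, dict] = {}
    clipped = 0

    # substances in a fixed order so the draw sequence is reproducible
    order = [t.substance for t in truth.all_truths()]
    for lab_idx, lab in enumerate(truth.lab_ids):
        lab_rng = np.random.default_rng(lab_seqs[lab_idx].spawn(1)[0])
        delta_lab = truth.sigma_lab * lab_rng.standard_normal()
        amp_lab = {
            s: math.exp(truths[s].amp_sigma_lab * lab_rng.standard_normal()) for s in order
        }
        exp_seqs = lab_seqs[lab_idx].spawn(truth.experiments_per_lab)
        for e in range(1, truth.experiments_per_lab + 1):
            exp_rng = np.random.default_rng(exp_seqs[e - 1].spawn(1)[0])
            delta_exp = truth.sigma_exp * exp_rng.standard_normal()
            amp = {
                s: amp_lab[s] * math.exp(truths[s].amp_sigma_exp * exp_rng.standard_normal())
                for s in order
            }
            offset = delta_lab + delta_exp
            plate_seqs = exp_seqs[e - 1].spawn(1 + len(truth.substances))
            specs = [(f"{lab}-E{e}-REF", ref_layout)] + [
                (f"{lab}-E{e}-{t.substance}", exp_layouts[t.substance]) for t in truth.substances
            ]
            for (pid, layout), pseq in zip(specs, plate_seqs):
                prng = np.random.default_rng(pseq)
                signal, tif, nclip = _plate_signal(
                    prng, layout, truths, amp, offset,
                    truth.sigma_well, truth.rlu_baseline, truth.rlu_cv,
                )
                clipped += nclip
                plates.append(PlateRead(lab, e, pid, "luciferase", layout, signal))
                if keep_true_if:
                    true_if_maps[pid] = tif

    if include_viability:
        vrng = np.random.default_rng(lab_seqs[-1].spawn(1)[0])
        vlab = truth.lab_ids[0]  # viability run once, by one participating lab
        for t in truth.all_truths():
            layout = viability_layout(t.substance, t.series)
            for e in range(1, truth.experiments_per_lab + 1):
                signal = {}
                for coord in layout.usable_wells:
                    a = layout.wells[coord]
                    frac = t.viability_percent(a.concentration) / 100.0 if a.role is WellRole.TEST_ITEM else 1.0
                    gain = 1.0 + truth.rlu_cv * vrng.standard_normal() if truth.rlu_cv > 0 else 1.0
                    v = truth.viability_baseline * frac * gain
                    if v < 0:
                        v = 0.0
                        clipped += 1
                    signal[coord] = v
                plates.append(
                    PlateRead(vlab, e, f"VIAB-E{e}-{t.substance}", "viability", layout, signal)
                )

    dataset = StudyDataset(plates, materials=[t.substance for t in truth.substances],
                           labs=list(truth.lab_ids))
    return SimulationResult(dataset, truth, clipped, true_if_maps)


# ---------------------------------------------------------------------------
# the default multi-lab study emulating the published pre-validation design


def default_nanomaterial_series(substance: str) -> DilutionSeries:
    """9 half-decade points spanning 0.01-100 ug/ml (the harmonized exposure
    range; the exact tested series was configurable in the protocol)."""
    return make_log_dilution_series(100.0, 0.01, 9, substance, UG_PER_ML)


def biorima_default_truth(seed: int = 0) -> StudyTruth:
    """7 labs x 3 experiments with an Ag-like strong-but-cytotoxic inducer, a
    TiO2-like inert material, and an Fe3O4-PEG-PLGA-like near-threshold
    material; curcumin reference peaking well above the effectiveness gate
    with a cytotoxic decline at the top dose.

    Between-lab differences act as a lognormal multiplier on the induction
    amplitude (per-plate solvent normalization removes additive gain
    offsets between labs, so what remains in real data is the magnitude of
    the response); within-lab noise is additive on the IF scale.
    """
    curcumin = SubstanceTruth(
        "curcumin", default_curcumin_series(),
        hill=(1.0, 14.0, -6.0, 1.3),
        cytotox=(5.0, -4.5, 1.5), cytotox_coupling=0.8,
        amp_sigma_lab=0.12, amp_sigma_exp=0.05,
    )
    dichlorvos = SubstanceTruth(
        "dichlorvos", default_dichlorvos_series(),
        hill=(1.0, 3.5, -5.7, 1.2),
        amp_sigma_lab=0.10, amp_sigma_exp=0.05,
    )
    mannitol = SubstanceTruth(
        "mannitol", default_mannitol_series(), hill=(1.0, 1.0, -4.0, 1.0)
    )
    ag = SubstanceTruth(
        "Ag", default_nanomaterial_series("Ag"),
        hill=(1.0, 6.5, 0.0, 1.5),
        cytotox=(5.0, 1.3, 3.0), cytotox_coupling=1.0,
        amp_sigma_lab=0.30, amp_sigma_exp=0.10,
    )
    tio2 = SubstanceTruth(
        "TiO2", default_nanomaterial_series("TiO2"),
        hill=(1.0, 1.0, 1.0, 1.0),
        cytotox=(40.0, 1.95, 4.0), cytotox_coupling=1.0,
    )
    fe3o4 = SubstanceTruth(
        "Fe3O4-PEG-PLGA", default_nanomaterial_series("Fe3O4-PEG-PLGA"),
        hill=(1.0, 1.55, 1.3, 1.5),
        cytotox=(0.0, 2.4, 2.0), cytotox_coupling=0.5,
        amp_sigma_lab=0.35, amp_sigma_exp=0.10,
    )
    return StudyTruth(
        labs=7,
        experiments_per_lab=3,
        substances=[fe3o4, ag, tio2],
        reference_truth=curcumin,
        positive_control_truth=dichlorvos,
        negative_control_truth=mannitol,
        sigma_lab=0.0,   # lab differences enter through the amplitude factors
        sigma_exp=0.13,
        sigma_well=0.16,
        rlu_baseline=20000.0,
        rlu_cv=0.08,
        seed=seed,
    )
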