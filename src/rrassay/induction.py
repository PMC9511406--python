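"""Induction factors, plate validity gating, and inducer classification.

The induction factor (IF) of a well is its raw luminescence divided by the
mean luminescence of the solvent-control wells of the *same* plate, so
between-plate reader-gain differences cancel by construction. A plate is
regarded as effective only when the curcumin reference series peaks at a
per-concentration mean IF strictly above 8; conditions with a mean IF of
1.5 or higher (inclusive) are classified as NRF2 inducers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import fmean, stdev
from typing import Iterable, Literal, Sequence

from .plate_model import PlateLayout, PlateRead, WellCoord, WellRole

INDUCTION_THRESHOLD = 1.5   # inclusive: "1.5 fold or higher"
EFFECTIVENESS_THRESHOLD = 8.0  # strict: curcumin IF "over 8"

Scope = Literal["within_experiment", "across_experiments"]


@dataclass
class InductionResult:
    """Per-well induction factors of one luciferase plate."""

    plate_id: str
    lab_id: str
    experiment_index: int
    layout: PlateLayout
    solvent_mean_rlu: float
    if_map: dict[WellCoord, float]

    def condition_means(self, role: WellRole) -> dict[tuple[str, float, str], float]:
        """Mean IF per (substance, concentration, unit) for wells of ``role``."""
        return {
            cond: fmean(self.if_map[c] for c in coords)
            for cond, coords in self.layout.conditions(role).items()
        }


@dataclass
class ValidityReport:
    plate_id: str
    lab_id: str
    experiment_index: int
    max_reference_if: float
    is_valid: bool
    positive_control_max_if: float | None = None
    negative_control_max_if: float | None = None


@dataclass
class ConditionSummary:
    """Mean +/- SD of induction factors for one condition.

    ``scope`` records whether replicates are wells of one experiment or
    per-experiment means across independent experiments; the SD is left
    missing (None) when n = 1 rather than stored as 0.
    """

    substance: str
    concentration: float
    unit: str
    mean_if: float
    sd_if: float | None
    n: int
    lab_id: str
    scope: Scope
    experiment_index: int | None = None
    role: WellRole = WellRole.TEST_ITEM


@dataclass
class InducerCall:
    substance: str
    concentration: float
    unit: str
    call: str  # "inducer" | "non_inducer"
    mean_if: float
    lab_id: str


def compute_induction_factors(plate: PlateRead) -> InductionResult:
    """Divide every usable well's RLU by the plate's mean solvent-control RLU."""
    if plate.assay != "luciferase":
        raise ValueError(f"expected a luciferase plate, got assay={plate.assay!r}")
    solvent = plate.layout.coords_with_role(WellRole.SOLVENT_CONTROL)
    solvent = [c for c in solvent if c in plate.signal]
    if len(solvent) < 2:
        raise ValueError("need at least 2 solvent-control wells with signal")
    denom = fmean(plate.signal[c] for c in solvent)
    if denom <= 0:
        raise ValueError("solvent-control mean RLU is zero")
    if_map = {c: v / denom for c, v in plate.signal.items()}
    return InductionResult(
        plate.plate_id, plate.lab_id, plate.experiment_index, plate.layout, denom, if_map
    )


def assess_validity(
    induction: InductionResult, effectiveness_threshold: float = EFFECTIVENESS_THRESHOLD
) -> ValidityReport:
    """Gate a plate on the peak per-concentration mean IF of the reference compound."""
    ref_means = induction.condition_means(WellRole.REFERENCE_COMPOUND)
    if not ref_means:
        raise ValueError(f"plate {induction.plate_id} has no reference-compound wells")
    pos = induction.condition_means(WellRole.POSITIVE_CONTROL)
    neg = induction.condition_means(WellRole.NEGATIVE_CONTROL)
    max_ref = max(ref_means.values())
    return ValidityReport(
        plate_id=induction.plate_id,
        lab_id=induction.lab_id,
        experiment_index=induction.experiment_index,
        max_reference_if=max_ref,
        is_valid=max_ref > effectiveness_threshold,
        positive_control_max_if=max(pos.values()) if pos else None,
        negative_control_max_if=max(neg.values()) if neg else None,
    )


_SUMMARY_ROLES = (
    WellRole.TEST_ITEM,
    WellRole.REFERENCE_COMPOUND,
    WellRole.POSITIVE_CONTROL,
    WellRole.NEGATIVE_CONTROL,
)


def _within_experiment(results: Sequence[InductionResult], roles) -> list[ConditionSummary]:
    out: list[ConditionSummary] = []
    # replicate wells of one condition within one (lab, experiment)
    groups: dict[tuple, list[float]] = {}
    for res in results:
        for role in roles:
            for (sub, conc, unit), coords in res.layout.conditions(role).items():
                key = (res.lab_id, res.experiment_index, role, sub, conc, unit)
                groups.setdefault(key, []).extend(res.if_map[c] for c in coords)
    for (lab, exp, role, sub, conc, unit), vals in groups.items():
        out.append(
            ConditionSummary(
                sub, conc, unit, fmean(vals), stdev(vals) if len(vals) > 1 else None,
                len(vals), lab, "within_experiment", exp, role,
            )
        )
    return out


def summarize_conditions(
    results: Iterable[InductionResult],
    scope: Scope = "across_experiments",
    roles: Sequence[WellRole] = _SUMMARY_ROLES,
) -> list[ConditionSummary]:
    """Summarize induction factors per condition and laboratory.

    ``within_experiment``: replicate wells of one experiment are averaged
    (one summary per lab x experiment x condition). ``across_experiments``:
    per-experiment means are first formed, then averaged; the SD is then the
    standard deviation over independent experiments — the intra-laboratory
    spread that feeds the precision analysis.
    """
    results = list(results)
    within = _within_experiment(results, roles)
    if scope == "within_experiment":
        return sorted(within, key=_summary_key)
    if scope != "across_experiments":
        raise ValueError(f"unknown scope {scope!r}")
    groups: dict[tuple, list[float]] = {}
    for s in within:
        key = (s.lab_id, s.role, s.substance, s.concentration, s.unit)
        groups.setdefault(key, []).append(s.mean_if)
    out = [
        ConditionSummary(
            sub, conc, unit, fmean(vals), stdev(vals) if len(vals) > 1 else None,
            len(vals), lab, "across_experiments", None, role,
        )
        for (lab, role, sub, conc, unit), vals in groups.items()
    ]
    return sorted(out, key=_summary_key)


def _summary_key(s: ConditionSummary):
    return (s.lab_id, s.role.value, s.substance, -s.concentration, s.experiment_index or 0)


def classify_inducers(
    summaries: Iterable[ConditionSummary], induction_threshold: float = INDUCTION_THRESHOLD
) -> list[InducerCall]:
    """Call each condition an inducer when its mean IF is >= the threshold (inclusive)."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no condition summaries to classify")
    return [
        InducerCall(
            s.substance, s.concentration, s.unit,
            "inducer" if s.mean_if >= induction_threshold else "non_inducer",
            s.mean_if, s.lab_id,
        )
        for s in summaries
    ]


def substance_calls(calls: Iterable[InducerCall]) -> dict[tuple[str, str], str]:
    """Substance-level call per lab: inducer if any concentration is an inducer."""
    out: dict[tuple[str, str], str] = {}
    for c in calls:
        key = (c.lab_id, c.substance)
        if out.get(key) != "inducer":
            out[key] = c.call
    return out
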