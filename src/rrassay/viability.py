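"""Viability normalization and cytotoxicity masking.

Viability-plate signals (resazurin fluorescence) are expressed as percent of
the mean signal of unexposed cells on the same plate. Concentrations whose
viability falls below a cutoff (default 70%, the common cytotoxicity
convention) can be flagged; the mask is only ever used to exclude points
from dose-response fitting, never to alter inducer classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable

from .plate_model import PlateRead, WellRole

VIABILITY_CUTOFF = 70.0

#: roles accepted as the unexposed reference, in order of preference
_REFERENCE_ROLES = (WellRole.UNTREATED_CONTROL, WellRole.SOLVENT_CONTROL)


@dataclass
class ViabilityResult:
    substance: str
    concentration: float
    unit: str
    percent_viability: float
    untreated_mean_signal: float
    lab_id: str = ""
    n: int = 0


@dataclass(frozen=True)
class CytotoxicityMask:
    substance: str
    flagged_concentrations: frozenset[float]
    viability_cutoff: float

    def masks(self, concentration: float) -> bool:
        return concentration in self.flagged_concentrations


def compute_viability(plate: PlateRead) -> list[ViabilityResult]:
    """Percent viability per condition: 100 x mean(signal | condition) / mean(signal | unexposed)."""
    if plate.assay != "viability":
        raise ValueError(f"expected a viability plate, got assay={plate.assay!r}")
    ref_coords: list = []
    for role in _REFERENCE_ROLES:
        ref_coords = [c for c in plate.layout.coords_with_role(role) if c in plate.signal]
        if ref_coords:
            break
    if len(ref_coords) < 2:
        raise ValueError("need at least 2 untreated/solvent-control wells")
    ref_mean = fmean(plate.signal[c] for c in ref_coords)
    if ref_mean <= 0:
        raise ValueError("unexposed-control mean signal is zero")
    out = []
    for (sub, conc, unit), coords in plate.layout.conditions(WellRole.TEST_ITEM).items():
        vals = [plate.signal[c] for c in coords if c in plate.signal]
        out.append(
            ViabilityResult(sub, conc, unit, 100.0 * fmean(vals) / ref_mean,
                            ref_mean, plate.lab_id, len(vals))
        )
    out.sort(key=lambda r: (r.substance, -r.concentration))
    return out


def pool_viability(results: Iterable[ViabilityResult]) -> list[ViabilityResult]:
    """Average percent viability per condition over replicate plates."""
    groups: dict[tuple[str, float, str], list[ViabilityResult]] = {}
    for r in results:
        groups.setdefault((r.substance, r.concentration, r.unit), []).append(r)
    out = [
        ViabilityResult(sub, conc, unit,
                        fmean(r.percent_viability for r in rs),
                        fmean(r.untreated_mean_signal for r in rs),
                        "", sum(r.n for r in rs))
        for (sub, conc, unit), rs in groups.items()
    ]
    out.sort(key=lambda r: (r.substance, -r.concentration))
    return out


def build_cytotoxicity_mask(
    viability: Iterable[ViabilityResult],
    cutoff: float = VIABILITY_CUTOFF,
    substance: str | None = None,
) -> CytotoxicityMask:
    """Flag every concentration whose percent viability is below ``cutoff``.

    ``viability`` must cover a single substance (or pass ``substance`` to
    filter a mixed list).
    """
    if not 0 <= cutoff <= 100:
        raise ValueError("cutoff must be in [0, 100]")
    results = [r for r in viability if substance is None or r.substance == substance]
    substances = {r.substance for r in results}
    if len(substances) != 1:
        raise ValueError(f"viability results cover {sorted(substances)}; pass substance= to select one")
    flagged = frozenset(r.concentration for r in results if r.percent_viability < cutoff)
    return CytotoxicityMask(substances.pop(), flagged, cutoff)


def build_cytotoxicity_masks(
    viability: Iterable[ViabilityResult], cutoff: float = VIABILITY_CUTOFF
) -> dict[str, CytotoxicityMask]:
    """Per-substance masks for a mixed list of viability results."""
    results = list(viability)
    return {
        sub: build_cytotoxicity_mask(results, cutoff, substance=sub)
        for sub in sorted({r.substance for r in results})
    }
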