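"""End-to-end pipeline: ingest -> validity -> induction -> viability -> fits -> precision.

``run_study`` is deterministic given the dataset and configuration; invalid
plates (curcumin peak at or below the effectiveness threshold) are excluded
from every downstream statistic but remain in the validity ledger, and the
written artifact set carries a manifest with content hashes so a run can be
audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import induction as ind
from . import interlab_stats as ils
from . import viability as via
from .dose_response import FitConstraints, fit_per_lab
from .plate_model import StudyDataset, WellRole

log = logging.getLogger("rrassay")


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run; round-trips via JSON."""

    induction_threshold: float = ind.INDUCTION_THRESHOLD
    effectiveness_threshold: float = ind.EFFECTIVENESS_THRESHOLD
    viability_cutoff: float = via.VIABILITY_CUTOFF
    scope: str = "across_experiments"
    apply_cytotoxicity_mask: bool = False
    constrain_bottom: bool = False
    include_controls_in_precision: bool = False
    precision_metric: str = "reproducibility"
    substances: list[str] | None = None

    def __post_init__(self) -> None:
        if min(self.induction_threshold, self.effectiveness_threshold, self.viability_cutoff) <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class StudyReport:
    config: RunConfig
    validity: pd.DataFrame           # one row per luciferase plate
    summaries: pd.DataFrame          # per-lab dose-response tables (mean +/- SD per condition)
    calls: pd.DataFrame              # per (lab, substance, concentration) inducer calls
    call_matrix: pd.DataFrame        # labs x substances, substance-level calls
    viability: pd.DataFrame          # per-condition percent viability (may be empty)
    masks: dict                      # substance -> CytotoxicityMask
    fits: pd.DataFrame               # per (lab, substance) 4PL parameters
    precision_cells: list            # list of PrecisionCell
    precision: ils.StudyPrecisionSummary | None
    dropped_labs: list[str]
    well_accounting: dict            # wells in = classified + excluded, with reasons


def _summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lab_id": [s.lab_id for s in summaries],
            "experiment": [s.experiment_index for s in summaries],
            "role": [s.role.value for s in summaries],
            "substance": [s.substance for s in summaries],
            "concentration": [s.concentration for s in summaries],
            "unit": [s.unit for s in summaries],
            "mean_if": [s.mean_if for s in summaries],
            "sd_if": [s.sd_if for s in summaries],
            "n": [s.n for s in summaries],
            "scope": [s.scope for s in summaries],
        }
    )


def run_study(dataset: StudyDataset, config: RunConfig | None = None) -> StudyReport:
    """Run the full round-robin analysis on a study dataset."""
    config = config or RunConfig()

    # 1. induction factors + validity gate on every luciferase plate
    results, validity_rows = [], []
    wells_in = wells_used = wells_excluded = 0
    for plate in dataset.luciferase_plates():
        wells_in += len(plate.signal)
        res = ind.compute_induction_factors(plate)
        rep = ind.assess_validity(res, config.effectiveness_threshold)
        validity_rows.append(
            {
                "plate_id": rep.plate_id, "lab_id": rep.lab_id, "experiment": rep.experiment_index,
                "max_reference_if": rep.max_reference_if, "is_valid": rep.is_valid,
                "positive_control_max_if": rep.positive_control_max_if,
                "negative_control_max_if": rep.negative_control_max_if,
            }
        )
        if rep.is_valid:
            results.append(res)
            wells_used += len(plate.signal)
        else:
            wells_excluded += len(plate.signal)
            log.warning(
                "plate %s (lab %s, experiment %d) invalid: curcumin peak IF %.2f <= %.2f; excluded",
                rep.plate_id, rep.lab_id, rep.experiment_index,
                rep.max_reference_if, config.effectiveness_threshold,
            )
    validity = pd.DataFrame(validity_rows)

    valid_labs = {r.lab_id for r in results}
    dropped = sorted(set(dataset.labs) - valid_labs)
    for lab in dropped:
        log.warning("lab %s has ZERO valid plates and is dropped from all statistics", lab)

    # 2. condition summaries and inducer calls (per lab, across experiments)
    summaries = ind.summarize_conditions(results, scope="across_experiments")
    test_summaries = [
        s for s in summaries
        if s.role is WellRole.TEST_ITEM
        and (config.substances is None or s.substance in config.substances)
    ]
    calls = ind.classify_inducers(test_summaries, config.induction_threshold) if test_summaries else []
    calls_df = pd.DataFrame(
        {
            "lab_id": [c.lab_id for c in calls],
            "substance": [c.substance for c in calls],
            "concentration": [c.concentration for c in calls],
            "unit": [c.unit for c in calls],
            "mean_if": [c.mean_if for c in calls],
            "call": [c.call for c in calls],
        }
    )
    matrix = (
        pd.Series(ind.substance_calls(calls)).unstack()
        if calls else pd.DataFrame()
    )

    # 3. viability + cytotoxicity masks
    via_results = []
    for plate in dataset.viability_plates():
        via_results.extend(via.compute_viability(plate))
    pooled = via.pool_viability(via_results) if via_results else []
    masks = via.build_cytotoxicity_masks(pooled, config.viability_cutoff) if pooled else {}
    viability_df = pd.DataFrame(
        {
            "substance": [r.substance for r in pooled],
            "concentration": [r.concentration for r in pooled],
            "unit": [r.unit for r in pooled],
            "percent_viability": [r.percent_viability for r in pooled],
            "n": [r.n for r in pooled],
        }
    )

    # 4. dose-response fits per (lab, substance)
    fit_masks = masks if config.apply_cytotoxicity_mask else None
    constraints = FitConstraints(fix_bottom=1.0 if config.constrain_bottom else None)
    fits = fit_per_lab(test_summaries, fit_masks, constraints)
    fits_df = pd.DataFrame(
        {
            "lab_id": [f.lab_id for f in fits],
            "substance": [f.substance for f in fits],
            "bottom": [f.bottom for f in fits],
            "top": [f.top for f in fits],
            "log10_ec50": [f.log10_ec50 for f in fits],
            "hill_slope": [f.hill_slope for f in fits],
            "rss": [f.residual_sum_squares for f in fits],
            "n_points": [f.n_points_used for f in fits],
            "converged": [f.converged for f in fits],
            "masked": [",".join(f"{c:g}" for c in sorted(f.masked_concentrations)) for f in fits],
        }
    )

    # 5. ISO 5725 precision on per-experiment condition means
    within = ind.summarize_conditions(results, scope="within_experiment")
    precision_substances = (
        None if config.include_controls_in_precision
        else (config.substances or dataset.materials)
    )
    if config.include_controls_in_precision:
        cell_input = within
    else:
        cell_input = [s for s in within if s.role is WellRole.TEST_ITEM]
    cells = ils.precision_cells_from_summaries(cell_input, precision_substances)
    precision = ils.summarize_study(cells, config.precision_metric) if cells else None

    return StudyReport(
        config=config,
        validity=validity,
        summaries=_summaries_frame(summaries),
        calls=calls_df,
        call_matrix=matrix,
        viability=viability_df,
        masks=masks,
        fits=fits_df,
        precision_cells=cells,
        precision=precision,
        dropped_labs=dropped,
        well_accounting={
            "wells_in": wells_in,
            "wells_classified": wells_used,
            "wells_excluded_invalid_plate": wells_excluded,
        },
    )


def write_report(report: StudyReport, out_dir) -> dict[str, str]:
    """Write all report artifacts as CSV/JSON/PNG plus a content-hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    save_df(report.validity, "validity.csv", index=False)
    save_df(report.summaries, "induction_summaries.csv", index=False)
    save_df(report.calls, "calls.csv", index=False)
    save_df(report.call_matrix, "call_matrix.csv")
    save_df(report.viability, "viability.csv", index=False)
    save_df(report.fits, "fits.csv", index=False)
    if report.precision is not None:
        save_df(report.precision.heatmap, "heatmap.csv", index=False)
        ils.plot_heatmap(report.precision, out / "heatmap.png")
        artifacts["heatmap.png"] = hashlib.sha256((out / "heatmap.png").read_bytes()).hexdigest()
        summary = {
            "mean_intra_lab_sd": report.precision.mean_intra_lab_sd,
            "mean_inter_lab_sd": report.precision.mean_inter_lab_sd,
            "range_inter_lab_sd": list(report.precision.range_inter_lab_sd),
            "metric": report.precision.metric,
            "dropped_labs": report.dropped_labs,
            "well_accounting": report.well_accounting,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        artifacts["summary.json"] = hashlib.sha256((out / "summary.json").read_bytes()).hexdigest()
    (out / "config.json").write_text(report.config.to_json())
    artifacts["config.json"] = hashlib.sha256((out / "config.json").read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(artifacts, indent=2, sort_keys=True))
    return artifacts
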