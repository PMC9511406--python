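"""Simulation-based validation experiments for the whole pipeline.

Each function runs the package end to end on synthetic studies with known
ground truth and returns the measured quantities as a flat dict. They back
the package's acceptance checks and the reproduction script, and are plain
library code — nothing here reads or writes files.
"""

from __future__ import annotations

import math
from statistics import fmean, median

import numpy as np

from . import induction as ind
from . import interlab_stats as ils
from .dose_response import fit_dose_response, hill_curve
from .induction import ConditionSummary
from .plate_model import UG_PER_ML, WellRole, make_log_dilution_series
from .synthetic_data import (
    StudyTruth,
    SubstanceTruth,
    biorima_default_truth,
    default_curcumin_series,
    default_dichlorvos_series,
    default_mannitol_series,
    simulate_study,
)

#: the published precision of the assay, used as generator ground truth for
#: the recovery experiment: intra-laboratory SD of per-experiment condition
#: means, and the cell reproducibility SD
INTRA_LAB_SD_TRUE = 0.16
INTER_LAB_SD_TRUE = 0.28


def _gated_induction(dataset, effectiveness=ind.EFFECTIVENESS_THRESHOLD):
    """Induction factors for every valid luciferase plate."""
    out = []
    for plate in dataset.luciferase_plates():
        res = ind.compute_induction_factors(plate)
        if ind.assess_validity(res, effectiveness).is_valid:
            out.append(res)
    return out


def recovery_truth(seed: int = 0, labs: int = 7, experiments: int = 3) -> StudyTruth:
    """A study whose variance components are the published precision values.

    Between-lab SD is sqrt(0.28^2 - 0.16^2) so the cell reproducibility SD is
    0.28; the within-lab components (experiment 0.1492, well 0.10) combine to
    an SD of 0.16 on per-experiment means of well triplicates. The single
    test material has a plain graded response with no amplitude heterogeneity
    or cytotoxicity, so every cell shares the same variance structure.
    """
    sigma_lab = math.sqrt(INTER_LAB_SD_TRUE**2 - INTRA_LAB_SD_TRUE**2)
    material = SubstanceTruth(
        "NB-1",
        make_log_dilution_series(100.0, 0.01, 9, "NB-1", UG_PER_ML),
        hill=(1.0, 2.5, 0.5, 1.0),
    )
    return StudyTruth(
        labs=labs,
        experiments_per_lab=experiments,
        substances=[material],
        reference_truth=SubstanceTruth("curcumin", default_curcumin_series(), hill=(1.0, 14.0, -6.0, 1.3)),
        positive_control_truth=SubstanceTruth("dichlorvos", default_dichlorvos_series(), hill=(1.0, 3.5, -5.7, 1.2)),
        negative_control_truth=SubstanceTruth("mannitol", default_mannitol_series(), hill=(1.0, 1.0, -4.0, 1.0)),
        sigma_lab=sigma_lab,
        sigma_exp=0.1492,
        sigma_well=0.10,
        rlu_cv=0.05,
        seed=seed,
    )


def variance_component_recovery(n_replicates: int = 500, seed: int = 0) -> dict:
    """Simulate the recovery study ``n_replicates`` times and average the
    pipeline's mean intra-lab and mean inter-lab (reproducibility) SDs."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    intra, inter = [], []
    for s in seeds:
        truth = recovery_truth(seed=int(s))
        result = simulate_study(truth, include_viability=False)
        results = _gated_induction(result.dataset)
        within = [
            w for w in ind.summarize_conditions(results, scope="within_experiment")
            if w.role is WellRole.TEST_ITEM
        ]
        cells = ils.precision_cells_from_summaries(within)
        summary = ils.summarize_study(cells)
        intra.append(summary.mean_intra_lab_sd)
        inter.append(summary.mean_inter_lab_sd)
    return {
        "mean_intra_lab_sd": fmean(intra),
        "mean_inter_lab_sd": fmean(inter),
        "true_intra_lab_sd": INTRA_LAB_SD_TRUE,
        "true_inter_lab_sd": INTER_LAB_SD_TRUE,
        "n_replicates": n_replicates,
    }


def _per_lab_condition_means(results):
    """lab -> substance -> {conc: mean IF across experiments} for test items."""
    out: dict[str, dict[str, dict[float, float]]] = {}
    for s in ind.summarize_conditions(results, scope="across_experiments"):
        if s.role is WellRole.TEST_ITEM:
            out.setdefault(s.lab_id, {}).setdefault(s.substance, {})[s.concentration] = s.mean_if
    return out


def ag_lab_outcome(conc_means: dict[float, float], threshold: float = ind.INDUCTION_THRESHOLD) -> bool:
    """One laboratory shows the Ag-like signature: an inducer call somewhere,
    a sub-threshold response at the lowest dose (dose dependence), and a
    clear decline at the top dose relative to the peak."""
    concs = sorted(conc_means)
    peak = max(conc_means.values())
    return (
        peak >= threshold
        and conc_means[concs[0]] < threshold
        and conc_means[concs[-1]] < 0.8 * peak
    )


def preset_reproduction(n_studies: int = 200, seed: int = 0) -> dict:
    """Qualitative round-robin outcomes over repeated default-preset studies.

    Measures, per simulated study: whether all 7 labs show the Ag signature
    (inducer, dose dependence, top-dose decline); whether every lab calls the
    TiO2-like material non-inducer at every concentration; and whether the
    Fe3O4-like material splits the laboratories across the 1.5 threshold.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_studies) % (2**31)
    ag_all, tio2_clean, fe_split = 0, 0, 0
    for s in seeds:
        truth = biorima_default_truth(seed=int(s))
        result = simulate_study(truth, include_viability=False)
        by_lab = _per_lab_condition_means(_gated_induction(result.dataset))
        labs = sorted(by_lab)
        if labs and all(ag_lab_outcome(by_lab[lab].get("Ag", {1.0: 0.0})) for lab in labs) and len(labs) == truth.labs:
            ag_all += 1
        if all(
            v < ind.INDUCTION_THRESHOLD
            for lab in labs
            for v in by_lab[lab].get("TiO2", {}).values()
        ):
            tio2_clean += 1
        fe_calls = {
            any(v >= ind.INDUCTION_THRESHOLD for v in by_lab[lab].get("Fe3O4-PEG-PLGA", {}).values())
            for lab in labs
        }
        if fe_calls == {True, False}:
            fe_split += 1
    return {
        "ag_all_labs_fraction": ag_all / n_studies,
        "tio2_clean_fraction": tio2_clean / n_studies,
        "fe3o4_split_fraction": fe_split / n_studies,
        "n_studies": n_studies,
    }


def false_inducer_rate(n_studies: int = 1000, noise_sd: float = 0.1, seed: int = 0) -> dict:
    """Per-condition false-inducer rate on studies with a flat truth at IF 1."""
    seeds = np.random.SeedSequence(seed).generate_state(n_studies) % (2**31)
    flat = SubstanceTruth(
        "inert", make_log_dilution_series(100.0, 0.01, 9, "inert", UG_PER_ML), hill=(1.0, 1.0, 1.0, 1.0)
    )
    n_calls = n_inducer = 0
    for s in seeds:
        truth = StudyTruth(
            labs=2, experiments_per_lab=3, substances=[flat],
            reference_truth=SubstanceTruth("curcumin", default_curcumin_series(), hill=(1.0, 14.0, -6.0, 1.3)),
            positive_control_truth=SubstanceTruth("dichlorvos", default_dichlorvos_series(), hill=(1.0, 3.5, -5.7, 1.2)),
            negative_control_truth=SubstanceTruth("mannitol", default_mannitol_series(), hill=(1.0, 1.0, -4.0, 1.0)),
            sigma_well=noise_sd, seed=int(s),
        )
        result = simulate_study(truth, include_viability=False)
        results = _gated_induction(result.dataset)
        summaries = [
            x for x in ind.summarize_conditions(results, scope="across_experiments")
            if x.role is WellRole.TEST_ITEM
        ]
        calls = ind.classify_inducers(summaries)
        n_calls += len(calls)
        n_inducer += sum(1 for c in calls if c.call == "inducer")
    return {
        "false_inducer_rate": n_inducer / n_calls,
        "n_conditions": n_calls,
        "n_studies": n_studies,
    }


def fit_recovery(
    n_replicates: int = 200,
    noise_sd: float = 0.1,
    n_replicate_wells: int = 3,
    seed: int = 0,
) -> dict:
    """4PL parameter recovery: exact on noiseless curves, median absolute
    errors under Gaussian IF noise (9 half-decade doses, well triplicates)."""
    true = dict(bottom=1.0, top=6.0, log10_ec50=math.log10(3.0), hill_slope=1.0)
    doses = make_log_dilution_series(100.0, 0.01, 9, "X", UG_PER_ML).concentrations

    def summaries_from(y):
        return [
            ConditionSummary("X", c, UG_PER_ML, float(m), None, n_replicate_wells, "L", "across_experiments")
            for c, m in zip(doses, y)
        ]

    clean = hill_curve(np.array(doses), **true)
    fit0 = fit_dose_response(summaries_from(clean))
    noiseless_err = max(
        abs(fit0.bottom - true["bottom"]) / true["bottom"],
        abs(fit0.top - true["top"]) / true["top"],
        abs(fit0.log10_ec50 - true["log10_ec50"]) / abs(true["log10_ec50"]),
        abs(fit0.hill_slope - true["hill_slope"]) / true["hill_slope"],
    )

    rng = np.random.default_rng(seed)
    ec50_err, top_err = [], []
    for _ in range(n_replicates):
        wells = clean[:, None] + noise_sd * rng.standard_normal((len(doses), n_replicate_wells))
        fit = fit_dose_response(summaries_from(wells.mean(axis=1)))
        ec50_err.append(abs(fit.log10_ec50 - true["log10_ec50"]))
        top_err.append(abs(fit.top - true["top"]))
    return {
        "noiseless_max_relative_error": noiseless_err,
        "median_abs_log10_ec50_error": median(ec50_err),
        "median_abs_top_error": median(top_err),
        "n_replicates": n_replicates,
    }


def consistency_test_calibration(
    n_replicates: int = 10000, p: int = 7, n: int = 3, seed: int = 0
) -> dict:
    """Cochran/Grubbs flag rates under a homoscedastic Gaussian null."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_replicates, p, n))
    cochran_flags = grubbs_flags = 0
    for rep in data:
        variances = rep.var(axis=1, ddof=1)
        _, flagged = ils.cochran_test(variances.tolist(), n)
        cochran_flags += flagged is not None
        _, flagged = ils.grubbs_test(rep.mean(axis=1).tolist())
        grubbs_flags += flagged is not None
    mc_se = math.sqrt(0.01 * 0.99 / n_replicates)
    return {
        "cochran_flag_rate": cochran_flags / n_replicates,
        "grubbs_flag_rate": grubbs_flags / n_replicates,
        "nominal_level": 0.01,
        "three_mc_se_bound": 0.01 + 3 * mc_se,
        "n_replicates": n_replicates,
    }
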