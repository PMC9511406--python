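"""ISO 5725-1/-2 repeatability and reproducibility of induction factors.

Each precision cell is one (material, concentration) combination. The
"values" entering a cell are per-experiment condition-mean induction
factors, normally three per laboratory. The one-way random-effects
decomposition gives

    s_r^2 = pooled (df-weighted) within-laboratory variance (repeatability),
    s_L^2 = max(0, var(lab means) - s_r^2 / n_bar)   (between-laboratory),
    s_R^2 = s_r^2 + s_L^2                            (reproducibility),

with n_bar the harmonic-mean replicate count, which reduces to the balanced
one-way ANOVA estimator when every laboratory contributes the same number of
replicates. Cochran's maximum-variance test and the single Grubbs test flag
inconsistent laboratories at the 1% level; flagged laboratories are never
removed automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._critical_values import cochran_critical_value, grubbs_critical_value
from .induction import ConditionSummary


@dataclass
class PrecisionCell:
    """ISO 5725 statistics for one material x concentration cell."""

    substance: str
    concentration: float
    unit: str
    lab_values: dict[str, tuple[float, ...]]
    p: int
    n_per_lab: dict[str, int]
    grand_mean: float
    s_r2: float
    s_L2: float
    s_R2: float
    intra_lab_sd: dict[str, float]
    cochran_C: float | None = None
    grubbs_G: float | None = None
    flags: set[tuple[str, str]] = field(default_factory=set)

    @property
    def s_r(self) -> float:
        return math.sqrt(self.s_r2)

    @property
    def s_L(self) -> float:
        return math.sqrt(self.s_L2)

    @property
    def s_R(self) -> float:
        return math.sqrt(self.s_R2)


@dataclass
class StudyPrecisionSummary:
    """Study-level aggregation of the per-cell precision statistics."""

    heatmap: pd.DataFrame  # long form: substance, concentration, unit, inter_lab_sd
    mean_intra_lab_sd: float
    mean_inter_lab_sd: float
    range_inter_lab_sd: tuple[float, float]
    metric: str  # "reproducibility" (s_R) or "between_lab" (s_L)

    def heatmap_wide(self) -> pd.DataFrame:
        return self.heatmap.pivot(index="substance", columns="concentration", values="inter_lab_sd")


def compute_precision_cell(
    lab_values: Mapping[str, Sequence[float]],
    substance: str = "",
    concentration: float = 0.0,
    unit: str = "",
) -> PrecisionCell:
    """Decompose one cell's per-lab replicate values into s_r, s_L, s_R.

    Laboratories with a single value contribute to the lab means (hence to
    s_L and the grand mean) but are excluded from the pooled within-lab
    variance and flagged ``single_value``.
    """
    labs = {lab: [float(v) for v in vals] for lab, vals in lab_values.items() if len(vals) > 0}
    if len(labs) < 2:
        raise ValueError("precision needs at least 2 laboratories with data")

    means = {lab: fmean(vals) for lab, vals in labs.items()}
    n_i = {lab: len(vals) for lab, vals in labs.items()}
    flags: set[tuple[str, str]] = {(lab, "single_value") for lab, n in n_i.items() if n < 2}

    intra = {
        lab: math.sqrt(sum((v - means[lab]) ** 2 for v in vals) / (len(vals) - 1))
        for lab, vals in labs.items()
        if len(vals) >= 2
    }
    if not intra:
        raise ValueError("no laboratory has >= 2 replicate values")

    # df-weighted pooled within-lab variance
    num = sum((n_i[lab] - 1) * intra[lab] ** 2 for lab in intra)
    den = sum(n_i[lab] - 1 for lab in intra)
    s_r2 = num / den

    p = len(labs)
    grand_mean = fmean(means.values())
    s_d2 = sum((m - grand_mean) ** 2 for m in means.values()) / (p - 1)
    n_bar = p / sum(1.0 / n for n in n_i.values())  # harmonic mean
    s_L2 = max(0.0, s_d2 - s_r2 / n_bar)
    s_R2 = s_r2 + s_L2

    cochran_C = None
    balanced_ns = {n_i[lab] for lab in intra}
    if len(intra) >= 2 and len(balanced_ns) == 1:
        try:
            ordered = sorted(intra)
            cochran_C, flagged = cochran_test([intra[lab] ** 2 for lab in ordered], balanced_ns.pop())
            if flagged is not None:
                flags.add((ordered[flagged], "cochran_outlier"))
        except ValueError:
            cochran_C = None  # outside the critical-value table

    grubbs_G = None
    if p >= 3:
        try:
            ordered = sorted(means)
            grubbs_G, flagged = grubbs_test([means[lab] for lab in ordered])
            if flagged is not None:
                flags.add((ordered[flagged], "grubbs_outlier"))
        except ValueError:
            grubbs_G = None

    return PrecisionCell(
        substance=substance,
        concentration=concentration,
        unit=unit,
        lab_values={lab: tuple(vals) for lab, vals in labs.items()},
        p=p,
        n_per_lab=n_i,
        grand_mean=grand_mean,
        s_r2=s_r2,
        s_L2=s_L2,
        s_R2=s_R2,
        intra_lab_sd=intra,
        cochran_C=cochran_C,
        grubbs_G=grubbs_G,
        flags=flags,
    )


def cochran_test(within_variances: Sequence[float], n: int) -> tuple[float, int | None]:
    """Cochran's maximum-variance consistency test at the 1% level.

    Returns (C, index of the flagged laboratory or None). C is the largest
    within-lab variance divided by the sum over laboratories; the critical
    value is the exact table entry for (p, n).
    """
    variances = [float(v) for v in within_variances]
    if len(variances) < 2:
        raise ValueError("Cochran test needs at least 2 laboratories")
    if any(v < 0 or not math.isfinite(v) for v in variances):
        raise ValueError("within-lab variances must be finite and >= 0")
    total = sum(variances)
    if total == 0:
        return 1.0 / len(variances), None  # all identical, nothing to flag
    imax = max(range(len(variances)), key=variances.__getitem__)
    c = variances[imax] / total
    crit = cochran_critical_value(len(variances), n)
    return c, (imax if c > crit else None)


def grubbs_test(lab_means: Sequence[float]) -> tuple[float | None, int | None]:
    """Single Grubbs test for one outlying laboratory mean, two-sided 1% level.

    Returns (G, index of the flagged laboratory or None); G is None when the
    spread of means is exactly zero.
    """
    means = [float(m) for m in lab_means]
    p = len(means)
    if p < 3:
        raise ValueError("Grubbs test needs at least 3 laboratories")
    m = fmean(means)
    s = math.sqrt(sum((x - m) ** 2 for x in means) / (p - 1))
    if s == 0:
        return None, None
    imax = max(range(p), key=lambda i: abs(means[i] - m))
    g = abs(means[imax] - m) / s
    crit = grubbs_critical_value(p)
    return g, (imax if g > crit else None)


def precision_cells_from_summaries(
    summaries: Iterable[ConditionSummary],
    substances: Sequence[str] | None = None,
) -> list[PrecisionCell]:
    """Build precision cells from within-experiment condition summaries.

    Expects ``scope='within_experiment'`` summaries (one mean per lab x
    experiment x condition); each cell then holds the per-experiment means
    of every laboratory for one (substance, concentration).
    """
    cells: dict[tuple[str, float, str], dict[str, list[float]]] = {}
    for s in summaries:
        if s.scope != "within_experiment":
            raise ValueError("precision cells are built from within_experiment summaries")
        if substances is not None and s.substance not in substances:
            continue
        cells.setdefault((s.substance, s.concentration, s.unit), {}).setdefault(s.lab_id, []).append(s.mean_if)
    out = []
    for (sub, conc, unit), lab_values in sorted(cells.items(), key=lambda kv: (kv[0][0], -kv[0][1])):
        if len(lab_values) < 2:
            continue
        out.append(compute_precision_cell(lab_values, sub, conc, unit))
    return out


def summarize_study(
    cells: Sequence[PrecisionCell], metric: str = "reproducibility"
) -> StudyPrecisionSummary:
    """Aggregate cells into the heatmap matrix and the headline means.

    ``mean_intra_lab_sd`` is the unweighted mean over every (lab, cell)
    within-laboratory SD; ``mean_inter_lab_sd`` averages the chosen
    inter-laboratory metric (reproducibility SD s_R by default, the
    between-lab component s_L on request) over cells.
    """
    if not cells:
        raise ValueError("no precision cells to summarize")
    if metric == "reproducibility":
        inter = [c.s_R for c in cells]
    elif metric == "between_lab":
        inter = [c.s_L for c in cells]
    else:
        raise ValueError("metric must be 'reproducibility' or 'between_lab'")
    intra = [sd for c in cells for sd in c.intra_lab_sd.values()]
    heatmap = pd.DataFrame(
        {
            "substance": [c.substance for c in cells],
            "concentration": [c.concentration for c in cells],
            "unit": [c.unit for c in cells],
            "inter_lab_sd": inter,
        }
    )
    return StudyPrecisionSummary(
        heatmap=heatmap,
        mean_intra_lab_sd=fmean(intra),
        mean_inter_lab_sd=fmean(inter),
        range_inter_lab_sd=(min(inter), max(inter)),
        metric=metric,
    )


def plot_heatmap(summary: StudyPrecisionSummary, path=None):
    """Render the inter-laboratory SD heatmap (darker = more variable)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = summary.heatmap_wide()
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * wide.shape[1], 1.0 + 0.6 * wide.shape[0]))
    im = ax.imshow(wide.to_numpy(), cmap="Greys", aspect="auto")
    ax.set_xticks(range(wide.shape[1]), [f"{c:g}" for c in wide.columns], rotation=45, ha="right")
    ax.set_yticks(range(wide.shape[0]), wide.index)
    ax.set_xlabel("concentration")
    fig.colorbar(im, ax=ax, label="inter-laboratory SD (IF units)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
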