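"""Four-parameter logistic (Hill) dose-response fitting of induction factors.

The model is the standard agonist-versus-response curve in log10 dose,

    IF(c) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - log10 c) * slope)),

fit by unweighted least squares on per-condition mean IFs (replicate-SD
weighting optional). The vehicle control (concentration 0) never enters the
fit, and bell-shaped responses caused by cytotoxicity at the top doses are
handled only by masking those concentrations, not by a biphasic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .induction import ConditionSummary
from .viability import CytotoxicityMask

#: jittered multi-start initialization uses this fixed, documented seed
MULTISTART_SEED = 20220905
N_RESTARTS = 4


@dataclass
class FitConstraints:
    """Optional constraints for the 4PL fit.

    ``fix_bottom=1.0`` pins the lower asymptote at the solvent-control IF.
    """

    fix_bottom: float | None = None
    weighted: bool = False  # 1/SD^2 weighting of condition means


@dataclass
class DoseResponseFit:
    substance: str
    lab_id: str
    bottom: float
    top: float
    log10_ec50: float
    hill_slope: float
    residual_sum_squares: float
    n_points_used: int
    converged: bool
    masked_concentrations: frozenset[float] = field(default_factory=frozenset)

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log10_ec50

    def predict(self, conc):
        return hill_curve(conc, self.bottom, self.top, self.log10_ec50, self.hill_slope)


def hill_curve(conc, bottom: float, top: float, log10_ec50: float, hill_slope: float):
    """Evaluate the 4PL curve; concentrations must be strictly positive."""
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0 (the vehicle control is excluded)")
    out = bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ec50 - np.log10(c)) * hill_slope))
    return float(out) if np.isscalar(conc) or np.ndim(conc) == 0 else out


def _residuals(theta, logc, y, w, fix_bottom):
    if fix_bottom is None:
        bottom, top, log_ec50, slope = theta
    else:
        bottom = fix_bottom
        top, log_ec50, slope = theta
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * slope))
    return (pred - y) * w


def fit_dose_response(
    summaries: Iterable[ConditionSummary],
    mask: CytotoxicityMask | None = None,
    constraints: FitConstraints | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit to one substance's condition means.

    Uses a data-driven start (bottom = min mean IF, top = max, EC50 at the
    dose nearest half-maximal response, slope 1) plus 4 jittered restarts
    from a fixed seed, keeping the best residual sum of squares. The
    ``converged`` flag reports optimizer success of the best start.
    """
    constraints = constraints or FitConstraints()
    summaries = [s for s in summaries if s.concentration > 0]
    if not summaries:
        raise ValueError("no positive-concentration summaries to fit")
    subs = {s.substance for s in summaries}
    labs = {s.lab_id for s in summaries}
    if len(subs) != 1:
        raise ValueError(f"summaries cover several substances: {sorted(subs)}")
    substance = subs.pop()
    lab_id = labs.pop() if len(labs) == 1 else "pooled"

    masked: frozenset[float] = frozenset()
    if mask is not None:
        if mask.substance != substance:
            raise ValueError(f"mask is for {mask.substance!r}, data for {substance!r}")
        masked = frozenset(s.concentration for s in summaries if mask.masks(s.concentration))
        summaries = [s for s in summaries if not mask.masks(s.concentration)]

    n_free = 3 if constraints.fix_bottom is not None else 4
    if len({s.concentration for s in summaries}) < max(4, n_free):
        raise ValueError("need at least 4 unmasked concentrations for a 4-parameter fit")

    conc = np.array([s.concentration for s in summaries])
    y = np.array([s.mean_if for s in summaries])
    logc = np.log10(conc)
    if constraints.weighted:
        sds = np.array([s.sd_if if s.sd_if else np.nan for s in summaries])
        fallback = np.nanmedian(sds) if np.any(np.isfinite(sds)) else 1.0
        sds = np.where(np.isfinite(sds) & (sds > 0), sds, max(fallback, 1e-9))
        w = 1.0 / sds
    else:
        w = np.ones_like(y)

    lo, hi = float(y.min()), float(y.max())
    half = (lo + hi) / 2.0
    ec50_guess = float(logc[np.argmin(np.abs(y - half))])
    base_bottom = constraints.fix_bottom if constraints.fix_bottom is not None else lo

    span = max(hi - lo, 1e-3)
    lspan = logc.max() - logc.min()
    rng = np.random.default_rng(MULTISTART_SEED)
    starts = [np.array([lo, hi, ec50_guess, 1.0])]
    for _ in range(N_RESTARTS):
        starts.append(
            np.array(
                [
                    lo + 0.2 * span * rng.standard_normal(),
                    hi + 0.2 * span * rng.standard_normal(),
                    ec50_guess + 0.25 * max(lspan, 1.0) * rng.standard_normal(),
                    float(10.0 ** rng.uniform(-0.5, 0.5)),
                ]
            )
        )

    lower = np.array([-np.inf, -np.inf, logc.min() - 3.0, -20.0])
    upper = np.array([np.inf, np.inf, logc.max() + 3.0, 20.0])
    if constraints.fix_bottom is not None:
        lower, upper = lower[1:], upper[1:]

    best = None
    for x0 in starts:
        if constraints.fix_bottom is not None:
            x0 = x0[1:]
        x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)
        try:
            res = least_squares(
                _residuals, x0, args=(logc, y, w, constraints.fix_bottom),
                bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    rss, res = best
    if constraints.fix_bottom is not None:
        bottom = constraints.fix_bottom
        top, log_ec50, slope = res.x
    else:
        bottom, top, log_ec50, slope = res.x
    # canonical orientation: negative slope with swapped asymptotes is the
    # same curve; report top >= bottom with the sign flip absorbed
    if bottom > top:
        bottom, top, slope = top, bottom, -slope
    return DoseResponseFit(
        substance=substance,
        lab_id=lab_id,
        bottom=float(bottom),
        top=float(top),
        log10_ec50=float(log_ec50),
        hill_slope=float(slope),
        residual_sum_squares=rss,
        n_points_used=len(y),
        converged=bool(res.success),
        masked_concentrations=masked,
    )


def fit_per_lab(
    summaries: Iterable[ConditionSummary],
    masks: dict[str, CytotoxicityMask] | None = None,
    constraints: FitConstraints | None = None,
) -> list[DoseResponseFit]:
    """One 4PL fit per (lab, substance); substances with too few
    concentrations are skipped."""
    groups: dict[tuple[str, str], list[ConditionSummary]] = {}
    for s in summaries:
        if s.concentration > 0:
            groups.setdefault((s.lab_id, s.substance), []).append(s)
    fits = []
    for (lab, sub), group in sorted(groups.items()):
        mask = (masks or {}).get(sub)
        try:
            fits.append(fit_dose_response(group, mask, constraints))
        except ValueError:
            continue
    return fits
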