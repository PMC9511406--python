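"""Normalize viability plates and flag cytotoxic concentrations.

Viability is the percent of the unexposed-control signal; concentrations
below the 70% cutoff can be masked out of dose-response fitting so that
cytotoxic signal collapse does not distort the curve.
"""

from rrassay import (
    biorima_default_truth,
    build_cytotoxicity_masks,
    compute_viability,
    pool_viability,
    simulate_study,
)

dataset = simulate_study(biorima_default_truth(seed=1)).dataset

results = []
for plate in dataset.viability_plates():
    results.extend(compute_viability(plate))
pooled = pool_viability(results)

print("percent viability (mean over replicate plates):")
for r in pooled:
    if r.substance in ("Ag", "TiO2", "Fe3O4-PEG-PLGA") and r.concentration >= 1:
        print(f"  {r.substance:15s} {r.concentration:7.2f} {r.unit}: {r.percent_viability:6.1f} %")

masks = build_cytotoxicity_masks(pooled, cutoff=70.0)
print("\nconcentrations flagged as cytotoxic (< 70% viability):")
for sub, mask in masks.items():
    flagged = ", ".join(f"{c:g}" for c in sorted(mask.flagged_concentrations)) or "none"
    print(f"  {sub:15s} {flagged}")
print("\nAg loses viability dose-dependently; TiO2 only at the top dose; the")
print("Fe3O4-PEG-PLGA material stays essentially non-cytotoxic.")
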