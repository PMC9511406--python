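"""Simulate a small round-robin study and normalize one plate to induction factors.

Each well's induction factor (IF) is its raw luminescence divided by the mean
luminescence of the solvent-control wells of the same plate, so IF = 1 means
"no different from the vehicle control" and reader gain cancels out.
"""

from rrassay import biorima_default_truth, compute_induction_factors, simulate_study
from rrassay.plate_model import WellRole

truth = biorima_default_truth(seed=1)
result = simulate_study(truth)
print(f"simulated {len(result.dataset.plates)} plates "
      f"({truth.labs} labs x {truth.experiments_per_lab} experiments, "
      f"{result.n_clipped_wells} wells clipped at 0)")

plate = next(p for p in result.dataset.luciferase_plates() if "Ag" in p.plate_id)
res = compute_induction_factors(plate)
print(f"\nplate {plate.plate_id}: solvent-control mean = {res.solvent_mean_rlu:.0f} RLU")
print("Ag condition means (IF is fold change over the solvent control):")
for (sub, conc, unit), mean_if in sorted(res.condition_means(WellRole.TEST_ITEM).items(),
                                         key=lambda kv: -kv[0][1]):
    print(f"  {sub} {conc:10.3f} {unit}: mean IF = {mean_if:5.2f}")
print("\nA rising IF with dose followed by a collapse at the top doses is the")
print("signature of an inducer whose highest concentrations are cytotoxic.")
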