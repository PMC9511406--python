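import math
from statistics import stdev

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrassay.induction import (
    ConditionSummary,
    assess_validity,
    classify_inducers,
    compute_induction_factors,
    substance_calls,
    summarize_conditions,
)
from rrassay.plate_model import WellCoord, WellRole

from conftest import tiny_plate


class TestInductionFactors:
    def test_direct_ratio_against_solvent_mean(self):
        res = compute_induction_factors(tiny_plate(solvent=(1000.0, 1000.0), test=(2000.0, 1500.0, 1000.0, 500.0)))
        assert res.if_map[WellCoord("E", 2)] == pytest.approx(2.0)
        assert res.solvent_mean_rlu == pytest.approx(1000.0)

    def test_solvent_wells_average_to_one(self, plate):
        res = compute_induction_factors(plate)
        solvent_ifs = [res.if_map[c] for c in plate.layout.coords_with_role(WellRole.SOLVENT_CONTROL)]
        assert sum(solvent_ifs) / len(solvent_ifs) == pytest.approx(1.0, abs=1e-12)
        # IF * solvent mean reconstructs the raw RLU
        for c, f in res.if_map.items():
            assert f * res.solvent_mean_rlu == pytest.approx(plate.signal[c])

    @given(gain=st.floats(1e-3, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_gain_invariance(self, gain):
        base = compute_induction_factors(tiny_plate())
        scaled_plate = tiny_plate()
        scaled_plate.signal = {c: v * gain for c, v in scaled_plate.signal.items()}
        scaled = compute_induction_factors(scaled_plate)
        for c in base.if_map:
            assert scaled.if_map[c] == pytest.approx(base.if_map[c], rel=1e-12)

    def test_zero_solvent_mean_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            compute_induction_factors(tiny_plate(solvent=(0.0, 0.0)))

    def test_viability_plate_rejected(self):
        with pytest.raises(ValueError, match="luciferase"):
            compute_induction_factors(tiny_plate(assay="viability"))


class TestValidity:
    def _plate_with_peak(self, peak_if):
        # solvent mean 1000 -> curcumin RLU = IF * 1000
        return tiny_plate(curcumin=(peak_if * 1000.0, 500.0, 400.0, 300.0))

    def test_peak_just_over_threshold_is_valid(self):
        rep = assess_validity(compute_induction_factors(self._plate_with_peak(8.01)))
        assert rep.max_reference_if == pytest.approx(8.01)
        assert rep.is_valid

    def test_peak_exactly_at_threshold_is_invalid(self):
        rep = assess_validity(compute_induction_factors(self._plate_with_peak(8.0)))
        assert not rep.is_valid

    def test_experimental_plate_has_no_control_fields(self):
        rep = assess_validity(compute_induction_factors(self._plate_with_peak(12.3)))
        assert rep.is_valid
        assert rep.positive_control_max_if is None
        assert rep.negative_control_max_if is None


class TestSummaries:
    def _results(self, experiment_means):
        """One lab, len(experiment_means) experiments; test wells set so the
        top-dose condition mean per experiment equals the given value."""
        out = []
        for e, m in enumerate(experiment_means, start=1):
            p = tiny_plate(test=(m * 1000.0, 900.0, 800.0, 700.0), experiment_index=e, plate_id=f"P{e}")
            out.append(compute_induction_factors(p))
        return out

    def test_across_experiments_mean_and_sd(self):
        summaries = summarize_conditions(self._results([2.0, 2.2, 2.4]), scope="across_experiments")
        top = next(s for s in summaries if s.substance == "X" and s.concentration == 100.0)
        assert top.mean_if == pytest.approx(2.2)
        assert top.sd_if == pytest.approx(stdev([2.0, 2.2, 2.4]))  # 0.2
        assert top.n == 3

    def test_single_experiment_sd_is_missing_not_zero(self):
        summaries = summarize_conditions(self._results([2.0]), scope="across_experiments")
        top = next(s for s in summaries if s.substance == "X" and s.concentration == 100.0)
        assert top.n == 1
        assert top.sd_if is None

    def test_identical_experiments_give_zero_sd(self):
        summaries = summarize_conditions(self._results([2.0, 2.0, 2.0]), scope="across_experiments")
        top = next(s for s in summaries if s.substance == "X" and s.concentration == 100.0)
        assert top.sd_if == pytest.approx(0.0, abs=1e-12)

    def test_within_experiment_scope_keeps_experiments_separate(self):
        summaries = summarize_conditions(self._results([2.0, 3.0]), scope="within_experiment")
        tops = [s for s in summaries if s.substance == "X" and s.concentration == 100.0]
        assert sorted(s.mean_if for s in tops) == pytest.approx([2.0, 3.0])
        assert all(s.experiment_index is not None for s in tops)


def _summary(mean_if, substance="X", conc=1.0, lab="L1"):
    return ConditionSummary(substance, conc, "ug/ml", mean_if, None, 3, lab, "across_experiments")


class TestClassification:
    def test_threshold_is_inclusive(self):
        calls = classify_inducers([_summary(1.5), _summary(1.49, conc=0.5)])
        assert [c.call for c in calls] == ["inducer", "non_inducer"]

    def test_flat_series_is_substance_level_non_inducer(self):
        calls = classify_inducers([_summary(1.0, conc=c) for c in (1.0, 10.0, 100.0)])
        assert substance_calls(calls) == {("L1", "X"): "non_inducer"}

    def test_any_inducing_concentration_makes_the_substance_an_inducer(self):
        calls = classify_inducers([_summary(1.0, conc=1.0), _summary(2.0, conc=10.0)])
        assert substance_calls(calls) == {("L1", "X"): "inducer"}

    @given(st.lists(st.floats(0.0, 5.0), min_size=1, max_size=8), st.floats(0.0, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_calls_are_monotone_in_mean_if(self, means, bump):
        before = classify_inducers([_summary(m, conc=i + 1.0) for i, m in enumerate(means)])
        after = classify_inducers([_summary(m + bump, conc=i + 1.0) for i, m in enumerate(means)])
        for b, a in zip(before, after):
            assert not (b.call == "inducer" and a.call == "non_inducer")
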