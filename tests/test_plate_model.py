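import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrassay.plate_model import (
    DilutionSeries,
    PlateLayout,
    WellAssignment,
    WellCoord,
    WellRole,
    make_log_dilution_series,
    read_plate_table,
    read_study,
    standard_biorima_layout,
    write_plate_table,
    write_study,
)
from rrassay.synthetic_data import biorima_default_truth, simulate_study

from conftest import tiny_layout, tiny_plate


class TestWellCoord:
    @pytest.mark.parametrize("label,usable", [
        ("A1", False), ("A6", False), ("H12", False), ("B1", False),
        ("G12", False), ("B2", True), ("G11", True), ("D7", True),
    ])
    def test_outer_frame_is_unusable(self, label, usable):
        assert WellCoord.parse(label).usable is usable

    def test_rejects_off_plate_coordinates(self):
        with pytest.raises(ValueError):
            WellCoord("I", 3)
        with pytest.raises(ValueError):
            WellCoord("B", 13)

    def test_parse_round_trip(self):
        assert str(WellCoord.parse("b10")) == "B10"


class TestDilutionSeries:
    @pytest.mark.parametrize("top,bottom,n,expected_ratio", [
        (1e-4, 1e-8, 5, 1e-1),            # exact decade steps
        (1e-4, 1e-8, 9, 10 ** -0.5),      # half-decade steps
        (100.0, 0.001, 6, 1e-1),
    ])
    def test_geometric_spacing(self, top, bottom, n, expected_ratio):
        s = make_log_dilution_series(top, bottom, n, "x", "M")
        assert len(s) == n
        assert s.concentrations[0] == pytest.approx(top)
        assert s.concentrations[-1] == pytest.approx(bottom)
        for a, b in zip(s.concentrations, s.concentrations[1:]):
            assert b / a == pytest.approx(expected_ratio, rel=1e-12)

    @given(
        top=st.floats(1e-9, 1e3), ratio=st.floats(1e-6, 0.99), n=st.integers(2, 12)
    )
    @settings(max_examples=100, deadline=None)
    def test_constant_ratio_and_strictly_decreasing(self, top, ratio, n):
        bottom = top * ratio
        s = make_log_dilution_series(top, bottom, n, "x", "M")
        ratios = [b / a for a, b in zip(s.concentrations, s.concentrations[1:])]
        assert all(r == pytest.approx(ratios[0], rel=1e-12) for r in ratios)
        assert all(b < a for a, b in zip(s.concentrations, s.concentrations[1:]))

    @pytest.mark.parametrize("top,bottom,n", [(0, 1e-8, 5), (1e-4, 0, 5), (1e-8, 1e-4, 5), (1e-4, 1e-8, 1)])
    def test_invalid_bounds(self, top, bottom, n):
        with pytest.raises(ValueError):
            make_log_dilution_series(top, bottom, n)


class TestLayouts:
    def test_experimental_layout_counts(self):
        series = make_log_dilution_series(100, 0.01, 9, "Ag", "ug/ml")
        layout = standard_biorima_layout("experimental", "Ag", series)
        roles = [a.role for a in layout.wells.values()]
        assert roles.count(WellRole.REFERENCE_COMPOUND) == 27
        assert roles.count(WellRole.TEST_ITEM) == 27
        assert roles.count(WellRole.SOLVENT_CONTROL) >= 6
        assert len(layout.wells) <= 60
        assert all(c.usable for c in layout.wells)

    def test_reference_layout_holds_chemical_controls(self):
        layout = standard_biorima_layout("reference")
        pos = layout.coords_with_role(WellRole.POSITIVE_CONTROL)
        neg = layout.coords_with_role(WellRole.NEGATIVE_CONTROL)
        assert pos and neg
        assert all(c.row in "EFG" for c in pos + neg)
        subs = {layout.wells[c].substance for c in pos}
        assert subs == {"dichlorvos"}

    def test_series_too_long_for_plate(self):
        series = make_log_dilution_series(100, 1e-7, 10, "X", "ug/ml")
        with pytest.raises(ValueError, match="does not fit|solvent"):
            standard_biorima_layout("experimental", "X", series)

    def test_reference_compound_confined_to_upper_rows(self):
        wells = {
            WellCoord("E", 2): WellAssignment(WellRole.REFERENCE_COMPOUND, "curcumin", 1e-6, "M"),
            WellCoord("B", 2): WellAssignment(WellRole.SOLVENT_CONTROL),
            WellCoord("B", 3): WellAssignment(WellRole.SOLVENT_CONTROL),
        }
        with pytest.raises(ValueError, match="rows B-D"):
            PlateLayout(wells)

    def test_outer_well_can_never_hold_a_role(self):
        with pytest.raises(ValueError, match="outer well"):
            PlateLayout({
                WellCoord("A", 1): WellAssignment(WellRole.SOLVENT_CONTROL),
                WellCoord("B", 2): WellAssignment(WellRole.SOLVENT_CONTROL),
                WellCoord("B", 3): WellAssignment(WellRole.SOLVENT_CONTROL),
            })

    def test_controls_have_zero_concentration_and_exposures_positive(self):
        with pytest.raises(ValueError):
            WellAssignment(WellRole.SOLVENT_CONTROL, concentration=1.0)
        with pytest.raises(ValueError):
            WellAssignment(WellRole.TEST_ITEM, "X", 0.0, "ug/ml")


class TestPlateIO:
    def test_long_form_value_maps_to_well(self):
        layout = tiny_layout()
        rows = ["row,col,value"]
        for coord in layout.usable_wells:
            rows.append(f"{coord.row},{coord.column},1000")
        plate = read_plate_table(io.StringIO("\n".join(rows)), layout)
        assert plate.signal[WellCoord("B", 2)] == 1000.0

    def test_outer_well_value_dropped_with_warning(self):
        layout = tiny_layout()
        rows = ["row,col,value", "A,1,500"]
        for coord in layout.usable_wells:
            rows.append(f"{coord.row},{coord.column},1000")
        with pytest.warns(UserWarning, match="A1"):
            plate = read_plate_table(io.StringIO("\n".join(rows)), layout)
        assert WellCoord("A", 1) not in plate.signal

    def test_missing_usable_well_is_an_error_naming_it(self):
        layout = tiny_layout()
        rows = ["row,col,value"]
        for coord in layout.usable_wells:
            if str(coord) != "E5":
                rows.append(f"{coord.row},{coord.column},1000")
        with pytest.raises(ValueError, match="E5"):
            read_plate_table(io.StringIO("\n".join(rows)), layout)

    @pytest.mark.parametrize("bad", ["abc", "-5"])
    def test_bad_signal_values_rejected(self, bad):
        layout = tiny_layout()
        rows = ["row,col,value"]
        for i, coord in enumerate(layout.usable_wells):
            rows.append(f"{coord.row},{coord.column},{bad if i == 0 else 1000}")
        with pytest.raises(ValueError):
            read_plate_table(io.StringIO("\n".join(rows)), layout)

    def test_grid_form_import(self):
        layout = tiny_layout()
        grid = [[""] + [str(c) for c in range(1, 13)]]
        for r in "ABCDEFGH":
            grid.append([r] + ["1000"] * 12)
        text = "\n".join(",".join(row) for row in grid)
        with pytest.warns(UserWarning):
            plate = read_plate_table(io.StringIO(text), layout)
        assert set(plate.signal) == set(layout.wells)

    def test_plate_round_trip(self, plate):
        buf = io.StringIO()
        write_plate_table(plate, buf)
        buf.seek(0)
        again = read_plate_table(buf, plate.layout)
        assert again.signal == plate.signal
        assert again.lab_id == plate.lab_id
        assert again.plate_id == plate.plate_id

    def test_study_round_trip(self, tmp_path):
        from dataclasses import replace

        truth = replace(biorima_default_truth(seed=5), labs=2, experiments_per_lab=2, lab_ids=[])
        dataset = simulate_study(truth).dataset
        write_study(dataset, tmp_path / "plates.csv", tmp_path / "layouts.csv")
        again = read_study(tmp_path / "plates.csv", tmp_path / "layouts.csv")
        assert len(again.plates) == len(dataset.plates)
        by_id = {p.plate_id: p for p in again.plates}
        for p in dataset.plates:
            q = by_id[p.plate_id]
            assert q.signal == p.signal
            assert {c: a.role for c, a in q.layout.wells.items()} == {
                c: a.role for c, a in p.layout.wells.items()
            }


class TestStudyStructure:
    def test_missing_reference_plate_rejected(self):
        from rrassay.plate_model import StudyDataset

        plates = [tiny_plate(plate_id=f"P{e}", experiment_index=e) for e in (1, 2)]
        plates += [tiny_plate(lab_id="LAB2", plate_id=f"Q{e}", experiment_index=e) for e in (1, 2)]
        with pytest.raises(ValueError, match="reference"):
            StudyDataset(plates)
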