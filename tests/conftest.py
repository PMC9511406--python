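"""Shared fixtures: tiny hand-built plates and a small synthetic study."""

from __future__ import annotations

import pytest

from rrassay.plate_model import (
    PlateLayout,
    PlateRead,
    WellAssignment,
    WellCoord,
    WellRole,
)


def tiny_layout() -> PlateLayout:
    """Minimal valid layout: 2 solvent wells, a 4-point curcumin series in
    row B, and a 4-point test series in row E."""
    wells = {}
    curcumin = [1e-5, 1e-6, 1e-7, 1e-8]
    test = [100.0, 10.0, 1.0, 0.1]
    for i, conc in enumerate(curcumin):
        wells[WellCoord("B", 2 + i)] = WellAssignment(WellRole.REFERENCE_COMPOUND, "curcumin", conc, "M")
    for i, conc in enumerate(test):
        wells[WellCoord("E", 2 + i)] = WellAssignment(WellRole.TEST_ITEM, "X", conc, "ug/ml")
    wells[WellCoord("B", 11)] = WellAssignment(WellRole.SOLVENT_CONTROL)
    wells[WellCoord("E", 11)] = WellAssignment(WellRole.SOLVENT_CONTROL)
    return PlateLayout(wells, "experimental")


def tiny_plate(
    solvent=(1000.0, 1000.0),
    curcumin=(9000.0, 12000.0, 3000.0, 1500.0),
    test=(2000.0, 1800.0, 1200.0, 1000.0),
    lab_id="LAB1",
    experiment_index=1,
    plate_id="P1",
    assay="luciferase",
) -> PlateRead:
    layout = tiny_layout()
    signal = {
        WellCoord("B", 11): solvent[0],
        WellCoord("E", 11): solvent[1],
    }
    for i, v in enumerate(curcumin):
        signal[WellCoord("B", 2 + i)] = v
    for i, v in enumerate(test):
        signal[WellCoord("E", 2 + i)] = v
    return PlateRead(lab_id, experiment_index, plate_id, assay, layout, signal)


@pytest.fixture
def plate() -> PlateRead:
    return tiny_plate()
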