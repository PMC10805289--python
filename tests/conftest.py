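import pytest

from frondlab.labware import DeckLayout, LabwareDefinition


@pytest.fixture
def toy_labware() -> LabwareDefinition:
    """A 24-well plate: 4 rows x 6 columns, 19 mm pitch, A1 at (15, 14)."""
    return LabwareDefinition(
        name="toy24",
        rows=4,
        columns=6,
        well_spacing_x=19.0,
        well_spacing_y=19.0,
        a1_offset_x=15.0,
        a1_offset_y=14.0,
        footprint_x=127.8,
        footprint_y=85.5,
        well_capacity_uL=3000.0,
        well_diameter=15.6,
        well_depth=17.0,
    )


@pytest.fixture
def toy_doc() -> dict:
    """The same 24-well plate as a flat labware-JSON document."""
    return {
        "name": "toy24",
        "rows": 4,
        "columns": 6,
        "well_spacing_x": 19.0,
        "well_spacing_y": 19.0,
        "a1_offset_x": 15.0,
        "a1_offset_y": 14.0,
        "footprint_x": 127.8,
        "footprint_y": 85.5,
        "well_capacity_uL": 3000.0,
    }


@pytest.fixture
def toy_deck() -> DeckLayout:
    """Six empty slots in a 3x2 grid of 140 x 100 mm bays (inside the envelope)."""
    origins = tuple(
        (140.0 * col, 100.0 * row) for row in range(3) for col in range(2)
    )
    return DeckLayout(slot_origins=origins)


@pytest.fixture
def loaded_deck(toy_deck, toy_labware) -> DeckLayout:
    """Deck with a reservoir in slot 0 and plates in slots 1-3."""
    toy_deck.add_labware(0, toy_labware, role="reservoir")
    for slot in (1, 2, 3):
        toy_deck.add_labware(slot, toy_labware, role="plate")
    return toy_deck
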