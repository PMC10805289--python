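"""Labware geometry and the six-slot deck.

Microplates, reservoirs and tip racks are described by a small flat JSON
dialect (rows/columns, well spacing, A1 offset, footprint) compatible in
spirit with OpenTrons labware definitions; the nested OpenTrons schema
(``wells``/``ordering``) is also accepted by extracting the grid parameters
from the per-well coordinates.

Coordinate convention: machine coordinates in mm, origin at the deck
front-left corner, +x right, +y rear.  Labware offsets are measured from the
labware front-left corner to the center of well A1; row letters increase
with +y, columns are 1-based, deck slots are 0-based.  By convention slot 0
holds the source reservoir (duckweed or media) and the remaining five slots
hold destination labware.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import AddressError, DeckError, GeometryError, LabwareFormatError

__all__ = [
    "LabwareDefinition",
    "WellAddress",
    "DeckLayout",
    "load_labware",
    "load_deck",
    "enumerate_wells",
    "well_location",
    "ROLES",
    "N_SLOTS",
]

#: Number of deck slots: the deck attachment houses six standard microplates.
N_SLOTS = 6

ROLES = ("reservoir", "plate", "tiprack", "sharps")

_GEOM_TOL = 1e-9

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class WellAddress:
    """A well identified the usual microplate way: row letter + 1-based column."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _ROW_LETTERS:
            raise AddressError(f"row letter must be A-Z, got {self.row!r}")
        if self.column < 1:
            raise AddressError(f"column must be >= 1, got {self.column}")

    @property
    def row_index(self) -> int:
        """0-based row index (A -> 0)."""
        return _ROW_LETTERS.index(self.row)

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = re.fullmatch(r"([A-Z])(\d+)", text.strip())
        if m is None:
            raise AddressError(f"cannot parse well address {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass(frozen=True)
class LabwareDefinition:
    """Geometry of one piece of labware: well grid, spacing, offsets, footprint.

    All lengths in mm, capacities in µL.
    """

    name: str
    rows: int
    columns: int
    well_spacing_x: float
    well_spacing_y: float
    a1_offset_x: float
    a1_offset_y: float
    footprint_x: float
    footprint_y: float
    well_capacity_uL: float
    well_diameter: float = 0.0
    well_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.columns < 1:
            raise LabwareFormatError(
                f"{self.name!r}: grid must be at least 1x1, got {self.rows}x{self.columns}"
            )
        if self.well_capacity_uL <= 0:
            raise LabwareFormatError(f"{self.name!r}: well capacity must be > 0")
        if self.columns > 1 and self.well_spacing_x <= 0:
            raise LabwareFormatError(f"{self.name!r}: well_spacing_x must be > 0")
        if self.rows > 1 and self.well_spacing_y <= 0:
            raise LabwareFormatError(f"{self.name!r}: well_spacing_y must be > 0")
        if self.a1_offset_x < 0 or self.a1_offset_y < 0:
            raise GeometryError(f"{self.name!r}: A1 offset must be non-negative")
        last_x = self.a1_offset_x + (self.columns - 1) * self.well_spacing_x
        last_y = self.a1_offset_y + (self.rows - 1) * self.well_spacing_y
        if last_x > self.footprint_x + _GEOM_TOL:
            raise GeometryError(
                f"{self.name!r}: last column at x={last_x:.3f} mm lies outside "
                f"footprint_x={self.footprint_x:.3f} mm"
            )
        if last_y > self.footprint_y + _GEOM_TOL:
            raise GeometryError(
                f"{self.name!r}: last row at y={last_y:.3f} mm lies outside "
                f"footprint_y={self.footprint_y:.3f} mm"
            )

    @property
    def n_wells(self) -> int:
        return self.rows * self.columns

    def has_well(self, well: WellAddress) -> bool:
        return well.row_index < self.rows and well.column <= self.columns

    def well_offset(self, well: WellAddress) -> tuple[float, float]:
        """(x, y) of a well center relative to the labware front-left corner."""
        if not self.has_well(well):
            raise AddressError(
                f"well {well} does not exist on {self.name!r} "
                f"({self.rows} rows x {self.columns} columns)"
            )
        x = self.a1_offset_x + (well.column - 1) * self.well_spacing_x
        y = self.a1_offset_y + well.row_index * self.well_spacing_y
        return (x, y)


_FLAT_REQUIRED = (
    "name",
    "rows",
    "columns",
    "well_spacing_x",
    "well_spacing_y",
    "a1_offset_x",
    "a1_offset_y",
    "footprint_x",
    "footprint_y",
    "well_capacity_uL",
)


def _load_json(source) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LabwareFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise LabwareFormatError("labware document must be a JSON object")
    return doc


def _from_opentrons(doc: dict) -> LabwareDefinition:
    # Nested vendor dialect: per-well coordinates under "wells", column-major
    # well names under "ordering", overall size under "dimensions".
    wells = doc["wells"]
    ordering = doc["ordering"]
    if not ordering or not ordering[0]:
        raise LabwareFormatError("ordering must contain at least one well")
    columns = len(ordering)
    rows = len(ordering[0])
    a1 = wells.get("A1")
    if a1 is None:
        raise LabwareFormatError("wells must contain A1")
    sx = abs(wells[ordering[1][0]]["x"] - a1["x"]) if columns > 1 else 0.0
    sy = abs(wells[ordering[0][1]]["y"] - a1["y"]) if rows > 1 else 0.0
    dims = doc.get("dimensions", {})
    meta = doc.get("metadata", {})
    name = doc.get("parameters", {}).get("loadName") or meta.get("displayName", "labware")
    return LabwareDefinition(
        name=name,
        rows=rows,
        columns=columns,
        well_spacing_x=sx,
        well_spacing_y=sy,
        a1_offset_x=a1["x"],
        a1_offset_y=a1["y"],
        footprint_x=dims.get("xDimension", a1["x"] + (columns - 1) * sx),
        footprint_y=dims.get("yDimension", a1["y"] + (rows - 1) * sy),
        well_capacity_uL=a1.get("totalLiquidVolume", 1.0),
        well_diameter=a1.get("diameter", 0.0),
        well_depth=a1.get("depth", 0.0),
    )


def load_labware(source) -> LabwareDefinition:
    """Load and validate a labware definition from a JSON file path or dict.

    Accepts the minimal flat schema (``rows``/``columns``/spacing/offset/
    footprint fields) or an OpenTrons-style nested document with ``wells``
    and ``ordering`` keys.

    Raises
    ------
    LabwareFormatError
        If the document is malformed; the message names the missing field.
    GeometryError
        If any well falls outside the labware footprint.
    """
    doc = _load_json(source)
    if "wells" in doc and "ordering" in doc:
        return _from_opentrons(doc)
    missing = [k for k in _FLAT_REQUIRED if k not in doc]
    if missing:
        raise LabwareFormatError(f"labware document is missing field(s): {', '.join(missing)}")
    kwargs = {k: doc[k] for k in _FLAT_REQUIRED}
    kwargs["well_diameter"] = doc.get("well_diameter", 0.0)
    kwargs["well_depth"] = doc.get("well_depth", 0.0)
    return LabwareDefinition(**kwargs)


def enumerate_wells(labware: LabwareDefinition, order: str = "row-major") -> list[WellAddress]:
    """All well addresses of a labware, row-major (A1, A2, ...) or column-major."""
    if order == "row-major":
        return [
            WellAddress(_ROW_LETTERS[r], c + 1)
            for r in range(labware.rows)
            for c in range(labware.columns)
        ]
    if order == "column-major":
        return [
            WellAddress(_ROW_LETTERS[r], c + 1)
            for c in range(labware.columns)
            for r in range(labware.rows)
        ]
    raise ValueError(f"order must be 'row-major' or 'column-major', got {order!r}")


@dataclass
class DeckLayout:
    """The six-slot machine deck.

    ``slot_origins`` holds the machine-coordinate (x, y) of each slot's
    front-left corner; slots are loaded with (labware, role) pairs.
    """

    slot_origins: tuple[tuple[float, float], ...]
    slots: list[Optional[tuple[LabwareDefinition, str]]] = field(
        default_factory=lambda: [None] * N_SLOTS
    )

    def __post_init__(self) -> None:
        if len(self.slot_origins) != N_SLOTS:
            raise DeckError(
                f"deck must define exactly {N_SLOTS} slot origins, got {len(self.slot_origins)}"
            )
        if len(self.slots) != N_SLOTS:
            raise DeckError(f"deck must have exactly {N_SLOTS} slots")

    def _check_slot(self, slot: int) -> None:
        if not 0 <= slot < N_SLOTS:
            raise DeckError(f"slot index must be 0-{N_SLOTS - 1}, got {slot}")

    def add_labware(
        self, slot: int, labware: LabwareDefinition, role: Optional[str] = None
    ) -> None:
        """Install labware in a slot.  A slot holds at most one labware."""
        self._check_slot(slot)
        if self.slots[slot] is not None:
            raise DeckError(f"slot {slot} already holds {self.slots[slot][0].name!r}")
        if role is None:
            role = "reservoir" if slot == 0 else "plate"
        if role not in ROLES:
            raise DeckError(f"role must be one of {ROLES}, got {role!r}")
        self.slots[slot] = (labware, role)

    def remove_labware(self, slot: int) -> LabwareDefinition:
        self._check_slot(slot)
        if self.slots[slot] is None:
            raise DeckError(f"slot {slot} is empty")
        labware, _ = self.slots[slot]
        self.slots[slot] = None
        return labware

    def labware_at(self, slot: int) -> LabwareDefinition:
        self._check_slot(slot)
        if self.slots[slot] is None:
            raise DeckError(f"slot {slot} is empty")
        return self.slots[slot][0]

    def occupied_slots(self) -> list[int]:
        return [i for i in range(N_SLOTS) if self.slots[i] is not None]


def load_deck(source) -> DeckLayout:
    """Load a deck configuration (six slot origins, mm) from JSON file or dict."""
    doc = _load_json(source)
    if "slot_origins" not in doc:
        raise LabwareFormatError("deck configuration is missing field: slot_origins")
    origins = tuple((float(x), float(y)) for x, y in doc["slot_origins"])
    return DeckLayout(slot_origins=origins)


def well_location(deck: DeckLayout, slot: int, well: WellAddress) -> tuple[float, float]:
    """Machine (x, y) in mm of a well center on the deck.

    x = slot_origin_x + a1_offset_x + (column - 1) * spacing_x, analogously
    for y with the 0-based row index.
    """
    labware = deck.labware_at(slot)  # raises DeckError if empty
    ox, oy = deck.slot_origins[slot]
    wx, wy = labware.well_offset(well)  # raises AddressError if absent
    return (ox + wx, oy + wy)
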