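"""Randomized plate layouts for genotype x media x replicate growth assays.

Given an experiment definition (name, genotype labels, media labels,
replicate count, labware), the layout generator builds the multiset of
genotype x media condition tokens, shuffles it with a seeded generator, and
deals the tokens row-major into the minimum number of plates.  Plates occupy
deck slots 1-5; slot 0 is reserved for the source reservoir.  Layouts are
persisted as human-readable JSON under an experiment directory tree so the
operator can inspect or hand-edit assignments, and a validator re-tallies
replicate counts after any edit.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .errors import CapacityError, LayoutLookupError, NameValidationError
from .labware import LabwareDefinition, WellAddress, enumerate_wells

__all__ = [
    "ExperimentSpec",
    "PlateAssignment",
    "PlateLayout",
    "randomize_layout",
    "save_layout",
    "load_layout",
    "validate_layout",
    "render_plate_map",
    "FORMAT_VERSION",
    "PLATE_SLOTS",
]

FORMAT_VERSION = 1

#: Deck slots available for destination plates (slot 0 holds the reservoir).
PLATE_SLOTS = (1, 2, 3, 4, 5)

_FORBIDDEN_NAME_CHARS = "_/\\"


def _check_name(name: str) -> None:
    if not name:
        raise NameValidationError("experiment name must be non-empty")
    bad = [c for c in _FORBIDDEN_NAME_CHARS if c in name]
    if bad:
        raise NameValidationError(
            f"experiment name {name!r} contains separator/path character(s) {bad}"
        )


@dataclass(frozen=True)
class ExperimentSpec:
    """Parameters of one growth assay: what grows in what, how many times."""

    name: str
    genotypes: tuple[str, ...]
    media: tuple[str, ...]
    replicates: int
    labware: LabwareDefinition
    seed: int = 0

    def __post_init__(self) -> None:
        _check_name(self.name)
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "media", tuple(self.media))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.genotypes or len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be non-empty and unique")
        if not self.media or len(set(self.media)) != len(self.media):
            raise ValueError("media labels must be non-empty and unique")

    @property
    def total_wells(self) -> int:
        return len(self.genotypes) * len(self.media) * self.replicates


@dataclass
class PlateAssignment:
    """One plate: its deck slot and the wells assigned to conditions."""

    plate: int  # 1-based plate index
    slot: int   # deck slot holding this plate
    wells: dict[str, tuple[str, str]]  # "A1" -> (genotype, media)


@dataclass
class PlateLayout:
    """The full randomized mapping of condition replicates to plate wells."""

    spec: ExperimentSpec
    plates: list[PlateAssignment]

    @property
    def total_wells(self) -> int:
        return sum(len(p.wells) for p in self.plates)

    def condition_of(self, plate: int, well: str) -> tuple[str, str]:
        """(genotype, media) assigned to a well, by 1-based plate index."""
        for p in self.plates:
            if p.plate == plate:
                if well not in p.wells:
                    raise LayoutLookupError(
                        f"well {well} on plate {plate} is not assigned in this layout"
                    )
                return p.wells[well]
        raise LayoutLookupError(f"layout has no plate {plate}")

    def assigned_wells(self) -> list[tuple[int, int, str, str, str]]:
        """Flat list of (plate, slot, well, genotype, media), plate order then row-major."""
        rows = []
        for p in self.plates:
            order = {str(w): i for i, w in enumerate(enumerate_wells(self.spec.labware))}
            for well in sorted(p.wells, key=order.__getitem__):
                g, m = p.wells[well]
                rows.append((p.plate, p.slot, well, g, m))
        return rows


def randomize_layout(
    spec: ExperimentSpec, plate_slots: Sequence[int] = PLATE_SLOTS
) -> PlateLayout:
    """Randomize replicate locations over the minimum number of plates.

    Deterministic for a fixed (spec, seed); different seeds permute the
    assignments.  Wells are filled contiguously in row-major order, so only
    the last plate may be partially filled.

    Raises
    ------
    CapacityError
        If the design needs more wells than the available plate slots hold.
    """
    wells_per_plate = spec.labware.n_wells
    total = spec.total_wells
    available = len(plate_slots) * wells_per_plate
    if total > available:
        raise CapacityError(
            f"design needs {total} wells but only {available} are available "
            f"({len(plate_slots)} plate slots x {wells_per_plate} wells)"
        )
    tokens = [
        (g, m)
        for g in spec.genotypes
        for m in spec.media
        for _ in range(spec.replicates)
    ]
    rng = random.Random(spec.seed)
    rng.shuffle(tokens)

    n_plates = math.ceil(total / wells_per_plate)
    well_order = [str(w) for w in enumerate_wells(spec.labware)]
    plates: list[PlateAssignment] = []
    for i in range(n_plates):
        chunk = tokens[i * wells_per_plate : (i + 1) * wells_per_plate]
        wells = {well_order[j]: cond for j, cond in enumerate(chunk)}
        plates.append(PlateAssignment(plate=i + 1, slot=plate_slots[i], wells=wells))
    return PlateLayout(spec=spec, plates=plates)


def _layout_to_doc(layout: PlateLayout) -> dict:
    spec = layout.spec
    return {
        "format_version": FORMAT_VERSION,
        "name": spec.name,
        "seed": spec.seed,
        "genotypes": list(spec.genotypes),
        "media": list(spec.media),
        "replicates": spec.replicates,
        "labware": asdict(spec.labware),
        "plates": [
            {
                "plate": p.plate,
                "slot": p.slot,
                "wells": {w: {"genotype": g, "media": m} for w, (g, m) in p.wells.items()},
            }
            for p in layout.plates
        ],
    }


def save_layout(layout: PlateLayout, directory) -> Path:
    """Write the experiment tree and layout JSON; returns the experiment dir.

    Creates ``<directory>/<name>/`` with ``layout/``, ``images/`` and
    ``results/`` subfolders and ``layout/experiment.json``.  Refuses to
    overwrite an existing experiment of the same name.
    """
    base = Path(directory) / layout.spec.name
    if base.exists():
        raise FileExistsError(f"experiment directory {base} already exists")
    for sub in ("layout", "images", "results"):
        (base / sub).mkdir(parents=True)
    path = base / "layout" / "experiment.json"
    path.write_text(json.dumps(_layout_to_doc(layout), indent=2) + "\n")
    return base


def load_layout(source) -> PlateLayout:
    """Load a layout from an experiment dir, a layout JSON path, or a dict."""
    if isinstance(source, dict):
        doc = source
    else:
        path = Path(source)
        if path.is_dir():
            path = path / "layout" / "experiment.json"
        doc = json.loads(path.read_text())
    labware = LabwareDefinition(**doc["labware"])
    spec = ExperimentSpec(
        name=doc["name"],
        genotypes=tuple(doc["genotypes"]),
        media=tuple(doc["media"]),
        replicates=doc["replicates"],
        labware=labware,
        seed=doc["seed"],
    )
    plates = [
        PlateAssignment(
            plate=p["plate"],
            slot=p["slot"],
            wells={w: (v["genotype"], v["media"]) for w, v in p["wells"].items()},
        )
        for p in doc["plates"]
    ]
    return PlateLayout(spec=spec, plates=plates)


def validate_layout(layout: PlateLayout) -> list[str]:
    """Re-tally a (possibly hand-edited) layout against its spec.

    Returns a list of human-readable problems; empty means the layout still
    satisfies the design invariants (exact replicate counts per condition,
    no unknown labels, no well assigned twice, minimal plate count).
    """
    spec = layout.spec
    problems: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for p in layout.plates:
        for well, (g, m) in p.wells.items():
            addr = WellAddress.parse(well)
            if not spec.labware.has_well(addr):
                problems.append(f"plate {p.plate}: well {well} not on {spec.labware.name!r}")
            if g not in spec.genotypes:
                problems.append(f"plate {p.plate} well {well}: unknown genotype {g!r}")
            if m not in spec.media:
                problems.append(f"plate {p.plate} well {well}: unknown media {m!r}")
            counts[(g, m)] = counts.get((g, m), 0) + 1
    for g in spec.genotypes:
        for m in spec.media:
            n = counts.pop((g, m), 0)
            if n != spec.replicates:
                problems.append(
                    f"condition ({g}, {m}) appears {n} times, expected {spec.replicates}"
                )
    for (g, m), n in counts.items():
        problems.append(f"condition ({g}, {m}) appears {n} times, expected 0")
    expected_plates = math.ceil(spec.total_wells / spec.labware.n_wells)
    if len(layout.plates) != expected_plates:
        problems.append(
            f"layout has {len(layout.plates)} plates, expected {expected_plates}"
        )
    return problems


def render_plate_map(layout: PlateLayout, plate: int) -> str:
    """Human-readable grid of one plate, each cell 'genotype/media' or '-'.

    Pure: does not mutate the layout.  ``plate`` is the 1-based plate index.
    """
    matching = [p for p in layout.plates if p.plate == plate]
    if not matching:
        raise IndexError(
            f"plate index must be one of {[p.plate for p in layout.plates]}, got {plate}"
        )
    assignment = matching[0]
    labware = layout.spec.labware
    cells: list[list[str]] = []
    for addr in enumerate_wells(labware):
        if addr.column == 1:
            cells.append([])
        cond = assignment.wells.get(str(addr))
        cells[-1].append(f"{cond[0]}/{cond[1]}" if cond else "-")
    width = max(len(c) for row in cells for c in row)
    header = "    " + " ".join(f"{c:^{width}}" for c in range(1, labware.columns + 1))
    lines = [f"plate {plate} (slot {assignment.slot})", header]
    for addr_row, row in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", cells):
        lines.append(f"  {addr_row} " + " ".join(f"{c:^{width}}" for c in row))
    return "\n".join(lines)
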