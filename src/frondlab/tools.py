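"""End-effector models: syringes, the OT-2 pipette, and transfer tools.

Each tool is a small parameterized configuration object plus functions that
turn lab intents (fill these wells with media, pick up a tip, move duckweed
into destination wells) into G-code command streams and operator prompts.
Streams execute against the virtual machine in tests and against a serial
transport on hardware.

The duckweed transfer loop is camera-verified: after each round, an
emptiness oracle (in production, frond segmentation on a fresh image of the
destination well; in tests, a stochastic stub) reports which wells are still
empty, and only those are retried, up to a configurable number of rounds.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Iterable, Optional, Sequence

from .design import PlateLayout
from .errors import (
    CapacityError,
    LayoutLookupError,
    SeekError,
    ToolConfigError,
    VolumeError,
)
from .gcode import (
    DEFAULT_CLEARANCE_Z,
    MotionCommand,
    axis_move,
    linear_move,
    safe_z_plan,
)
from .labware import DeckLayout, WellAddress, well_location

__all__ = [
    "SyringeConfig",
    "PipetteConfig",
    "TransferReport",
    "WellOutcome",
    "FillPlan",
    "PickupResult",
    "TRANSFER_TOOLS",
    "volume_to_travel",
    "aspirate",
    "dispense",
    "fill_wells",
    "pickup_tip",
    "transfer_duckweed",
    "manual_transfer_instructions",
    "StochasticEmptinessOracle",
]

#: Tools usable for duckweed transfer: a standard inoculation loop, a custom
#: loop whose head sits at a right angle to the handle (for heavy multi-frond
#: ramets such as *Spirodela polyrhiza*), and a needle syringe.
TRANSFER_TOOLS = ("loop", "angled_loop", "syringe")


@dataclass(frozen=True)
class SyringeConfig:
    """A plunger-driven syringe tool (10cc or 50cc barrel).

    ``travel_per_uL`` is the plunger-axis calibration constant in mm/µL;
    the default used in fixtures (50cc barrel, 0.0012 mm/µL) is a fixture
    value, not a measured calibration.
    """

    capacity_uL: float = 50000.0
    travel_per_uL: float = 0.0012
    current_volume: float = 0.0
    plunger_axis: str = "E"
    aspirate_feedrate: float = 300.0
    dispense_feedrate: float = 300.0

    def __post_init__(self) -> None:
        if self.travel_per_uL <= 0:
            raise ToolConfigError("travel_per_uL must be > 0")
        if not (0.0 <= self.current_volume <= self.capacity_uL):
            raise VolumeError(
                f"current_volume {self.current_volume} outside [0, {self.capacity_uL}]"
            )


def volume_to_travel(config: SyringeConfig, volume: float) -> float:
    """Plunger travel (mm) for a volume (µL); exactly linear."""
    if volume < 0:
        raise VolumeError(f"volume must be >= 0, got {volume}")
    return volume * config.travel_per_uL


def aspirate(config: SyringeConfig, volume: float) -> tuple[SyringeConfig, MotionCommand]:
    """Draw liquid in: returns the updated syringe and the plunger command."""
    if volume < 0:
        raise VolumeError(f"volume must be >= 0, got {volume}")
    new_volume = config.current_volume + volume
    if new_volume > config.capacity_uL + 1e-9:
        raise VolumeError(
            f"aspirating {volume} µL would exceed capacity "
            f"({config.current_volume} + {volume} > {config.capacity_uL})"
        )
    cmd = axis_move(
        config.plunger_axis,
        volume_to_travel(config, new_volume),
        feedrate=config.aspirate_feedrate,
    )
    return replace(config, current_volume=new_volume), cmd


def dispense(config: SyringeConfig, volume: float) -> tuple[SyringeConfig, MotionCommand]:
    """Expel liquid: returns the updated syringe and the plunger command."""
    if volume < 0:
        raise VolumeError(f"volume must be >= 0, got {volume}")
    new_volume = config.current_volume - volume
    if new_volume < -1e-9:
        raise VolumeError(
            f"dispensing {volume} µL would underflow "
            f"({config.current_volume} - {volume} < 0)"
        )
    cmd = axis_move(
        config.plunger_axis,
        volume_to_travel(config, max(new_volume, 0.0)),
        feedrate=config.dispense_feedrate,
    )
    return replace(config, current_volume=max(new_volume, 0.0)), cmd


@dataclass
class FillPlan:
    """A media-fill command stream with its operator prompts and bookkeeping."""

    commands: list[MotionCommand]
    prompts: list[str]
    n_batches: int
    total_dispensed: float
    syringe: SyringeConfig
    volume_trace: list[float]  # syringe volume after each plunger command


def fill_wells(
    deck: DeckLayout,
    layout: PlateLayout,
    media_name: str,
    volume_per_well: float,
    syringe: SyringeConfig,
    *,
    reservoir_slot: int = 0,
    reservoir_well: str = "A1",
    clearance_z: float = DEFAULT_CLEARANCE_Z,
    reservoir_z: float = 5.0,
    dispense_z: float = 8.0,
    loaded_media: Optional[str] = None,
) -> FillPlan:
    """Plan filling every well assigned to one media with a fixed volume.

    For each target well: safe-z travel to the reservoir, aspirate (batching
    refills whenever the remaining syringe volume cannot cover the next
    dispense), safe-z travel to the well, dispense ``volume_per_well``.
    When ``loaded_media`` differs from ``media_name``, the plan starts with
    an operator prompt to swap the reservoir.

    The dispense depth, reservoir needle depth and travel clearance are
    configuration; defaults are fixture values.
    """
    conditions = {m for p in layout.plates for (_, m) in p.wells.values()}
    if media_name not in conditions:
        raise LayoutLookupError(
            f"media {media_name!r} not present in layout (has {sorted(conditions)})"
        )
    if volume_per_well <= 0:
        raise VolumeError("volume_per_well must be > 0")
    capacity = layout.spec.labware.well_capacity_uL
    if volume_per_well > capacity:
        raise CapacityError(
            f"volume_per_well {volume_per_well} µL exceeds well capacity {capacity} µL"
        )

    targets = [
        (slot, well)
        for (_, slot, well, _, m) in layout.assigned_wells()
        if m == media_name
    ]
    prompts: list[str] = []
    if targets and loaded_media != media_name:
        prompts.append(
            f"Swap the reservoir in slot {reservoir_slot} to media {media_name!r}, "
            "then confirm to continue."
        )
    commands: list[MotionCommand] = []
    volume_trace: list[float] = []
    reservoir_xy = well_location(deck, reservoir_slot, WellAddress.parse(reservoir_well))
    position = (reservoir_xy[0], reservoir_xy[1], clearance_z)
    n_batches = 0
    total_dispensed = 0.0
    remaining = len(targets) * volume_per_well
    for slot, well in targets:
        if syringe.current_volume < volume_per_well - 1e-9:
            target = (reservoir_xy[0], reservoir_xy[1], reservoir_z)
            commands.extend(safe_z_plan(position, target, clearance_z))
            refill = min(syringe.capacity_uL - syringe.current_volume, remaining)
            syringe, cmd = aspirate(syringe, refill)
            commands.append(cmd)
            volume_trace.append(syringe.current_volume)
            position = target
            n_batches += 1
        wx, wy = well_location(deck, slot, WellAddress.parse(well))
        target = (wx, wy, dispense_z)
        commands.extend(safe_z_plan(position, target, clearance_z))
        syringe, cmd = dispense(syringe, volume_per_well)
        commands.append(cmd)
        volume_trace.append(syringe.current_volume)
        position = target
        total_dispensed += volume_per_well
        remaining -= volume_per_well
    return FillPlan(
        commands=commands,
        prompts=prompts,
        n_batches=n_batches,
        total_dispensed=total_dispensed,
        syringe=syringe,
        volume_trace=volume_trace,
    )


@dataclass(frozen=True)
class PipetteConfig:
    """A single-channel OT-2 pipette on the tool changer.

    Tip pickup is sensed by a limit switch behind the toolplate flexure:
    the platform advances in small z increments until the virtual switch
    triggers at ``contact_z``.
    """

    model: str = "P300"
    min_volume: float = 20.0
    max_volume: float = 300.0
    has_tip: bool = False
    tip_seek_step: float = 0.5
    contact_z: float = 4.0
    max_seek_travel: float = 20.0

    def __post_init__(self) -> None:
        if self.tip_seek_step <= 0:
            raise ToolConfigError("tip_seek_step must be > 0")
        if not (0 < self.min_volume <= self.max_volume):
            raise ToolConfigError("need 0 < min_volume <= max_volume")


@dataclass
class PickupResult:
    pipette: PipetteConfig
    commands: list[MotionCommand]
    n_steps: int


def pickup_tip(
    pipette: PipetteConfig,
    tip_xy: tuple[float, float],
    start_z: float,
    *,
    clearance_z: float = DEFAULT_CLEARANCE_Z,
    seek_feedrate: float = 120.0,
) -> PickupResult:
    """Approach a rack tip and press-fit it by stepping toward the switch.

    The stream aligns over the tip at ``start_z`` and then descends in
    ``tip_seek_step`` increments until z reaches ``contact_z`` (the virtual
    limit switch).  The number of increments is
    ``ceil((start_z - contact_z) / tip_seek_step)``; zero if already in
    contact.

    Raises
    ------
    ToolConfigError
        If a tip is already attached.
    SeekError
        If the required travel exceeds ``max_seek_travel`` (switch never
        triggers within the configured bound).
    """
    if pipette.has_tip:
        raise ToolConfigError("pickup_tip called with a tip already attached")
    if start_z < pipette.contact_z:
        raise SeekError(
            f"start_z {start_z} is below contact_z {pipette.contact_z}; refuse to plunge"
        )
    travel = start_z - pipette.contact_z
    if travel > pipette.max_seek_travel + 1e-9:
        raise SeekError(
            f"contact at {pipette.contact_z} mm needs {travel:.3f} mm of seek travel, "
            f"more than max_seek_travel {pipette.max_seek_travel} mm"
        )
    commands = safe_z_plan(
        (tip_xy[0], tip_xy[1], clearance_z), (tip_xy[0], tip_xy[1], start_z), clearance_z
    )
    n_steps = math.ceil(round(travel / pipette.tip_seek_step, 9))
    z = start_z
    for _ in range(n_steps):
        z = max(z - pipette.tip_seek_step, pipette.contact_z)
        commands.append(linear_move(z=z, feedrate=seek_feedrate))
    return PickupResult(
        pipette=replace(pipette, has_tip=True), commands=commands, n_steps=n_steps
    )


@dataclass
class WellOutcome:
    attempts: int
    status: str  # "occupied" | "empty"


@dataclass
class TransferReport:
    """Per-well tally of the camera-verified transfer retry loop."""

    wells: dict[Hashable, WellOutcome]
    rounds: int
    tool: str

    @property
    def n_occupied(self) -> int:
        return sum(1 for o in self.wells.values() if o.status == "occupied")

    @property
    def n_empty(self) -> int:
        return sum(1 for o in self.wells.values() if o.status == "empty")


def transfer_duckweed(
    source: Hashable,
    destination_wells: Sequence[Hashable],
    tool: str,
    max_rounds: int = 3,
    emptiness_oracle: Callable[[Hashable], bool] = None,
    attempt_hook: Optional[Callable[[Hashable, int], None]] = None,
) -> TransferReport:
    """Move duckweed from a source into destination wells with verification.

    Round 1 attempts every destination well.  After each round the
    ``emptiness_oracle`` (image-based in production, a stub in tests) is
    queried for every well attempted that round; wells still empty are
    retried in the next round.  The loop stops when no wells are empty or
    ``max_rounds`` is reached.  ``attempt_hook(well, round)`` is called once
    per physical attempt, letting callers drive actual motion.

    Returns a report with per-well attempt counts and final status.
    """
    if tool not in TRANSFER_TOOLS:
        raise ToolConfigError(f"unknown transfer tool {tool!r}; choose from {TRANSFER_TOOLS}")
    if max_rounds < 1:
        raise ToolConfigError("max_rounds must be >= 1")
    if emptiness_oracle is None:
        raise ToolConfigError("an emptiness oracle is required for verified transfer")

    outcomes = {w: WellOutcome(attempts=0, status="empty") for w in destination_wells}
    pending = list(destination_wells)
    rounds = 0
    while pending and rounds < max_rounds:
        rounds += 1
        for well in pending:
            outcomes[well].attempts += 1
            if attempt_hook is not None:
                attempt_hook(well, rounds)
        still_empty = []
        for well in pending:
            if emptiness_oracle(well):
                still_empty.append(well)
            else:
                outcomes[well].status = "occupied"
        pending = still_empty
    return TransferReport(wells=outcomes, rounds=rounds, tool=tool)


def manual_transfer_instructions(layout: PlateLayout) -> list[str]:
    """Just-in-time text instructions for tweezer transfer by a human operator.

    One line per assigned well, in plate order then row-major well order.
    """
    return [
        f"Using tweezers, place one {genotype} ramet into plate {plate} "
        f"(slot {slot}) well {well}  [{media}]."
        for (plate, slot, well, genotype, media) in layout.assigned_wells()
    ]


class StochasticEmptinessOracle:
    """Test stub for camera verification: each attempt succeeds with fixed odds.

    Every oracle query for a not-yet-occupied well draws success with
    probability ``success_prob`` (per-tool transfer reliability); once a well
    is occupied it stays occupied.  Seeded and deterministic.
    """

    def __init__(self, success_prob: float, seed: int = 0):
        if not 0.0 <= success_prob <= 1.0:
            raise ToolConfigError("success_prob must be in [0, 1]")
        self.success_prob = success_prob
        self._rng = random.Random(seed)
        self._occupied: set[Hashable] = set()
        self.queries = 0

    def __call__(self, well: Hashable) -> bool:
        self.queries += 1
        if well in self._occupied:
            return False
        if self._rng.random() < self.success_prob:
            self._occupied.add(well)
            return False
        return True
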