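"""G-code generation and a rule-checking virtual machine.

The motion platform speaks Duet/RepRapFirmware-style G-code over a serial
link: ``G28`` homes, ``G0`` travels, ``T<n>``/``T-1`` select and deselect
tools.  This module renders :class:`MotionCommand` objects to byte-stable
text (3-decimal coordinates), parses them back, and replays command streams
against a :class:`MachineState` that enforces the legality rules a real
firmware would (home before moving, stay inside the axis envelope, park the
active tool before picking up another).

Hardware is optional by construction: anything implementing the transport
contract ``send(line) -> reply`` can execute a stream.  The bundled
:class:`VirtualMachine` is the default transport; a pyserial-backed
transport can be supplied by the caller for a physical machine.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import CommandError, MachineRangeError, MachineViolationError

__all__ = [
    "MotionCommand",
    "MachineState",
    "Violation",
    "emit_gcode",
    "parse_gcode",
    "virtual_execute",
    "safe_z_plan",
    "VirtualMachine",
    "home",
    "linear_move",
    "axis_move",
    "tool_select",
    "tool_deselect",
    "DEFAULT_AXIS_LIMITS",
    "DEFAULT_CLEARANCE_Z",
    "load_machine_config",
]

VERBS = ("home", "linear_move", "axis_move", "tool_select", "tool_deselect")

#: Default machine envelope (mm) when no machine config is given.
DEFAULT_AXIS_LIMITS: dict[str, tuple[float, float]] = {
    "X": (0.0, 300.0),
    "Y": (0.0, 300.0),
    "Z": (0.0, 300.0),
}

#: Default z clearance (mm) for safe travel moves.
DEFAULT_CLEARANCE_Z = 30.0


@dataclass(frozen=True)
class MotionCommand:
    """One machine instruction; serializes to exactly one G-code line."""

    verb: str
    x: Optional[float] = None
    y: Optional[float] = None
    z: Optional[float] = None
    feedrate: Optional[float] = None
    tool: Optional[int] = None
    axis: Optional[str] = None      # auxiliary axis letter for axis_move (e.g. "E")
    target: Optional[float] = None  # auxiliary axis target position, mm

    def __post_init__(self) -> None:
        if self.verb not in VERBS:
            raise CommandError(f"unknown verb {self.verb!r}")
        if self.verb == "axis_move":
            if not self.axis or self.axis in "XYZ" or len(self.axis) != 1:
                raise CommandError("axis_move needs a single non-XYZ axis letter")
            if self.target is None:
                raise CommandError("axis_move needs a target position")
        if self.verb == "tool_select" and (self.tool is None or self.tool < 0):
            raise CommandError("tool_select needs a non-negative tool id")


def home() -> MotionCommand:
    return MotionCommand("home")


def linear_move(x=None, y=None, z=None, feedrate=None) -> MotionCommand:
    if x is None and y is None and z is None:
        raise CommandError("linear_move needs at least one of x, y, z")
    return MotionCommand("linear_move", x=x, y=y, z=z, feedrate=feedrate)


def axis_move(axis: str, target: float, feedrate=None) -> MotionCommand:
    return MotionCommand("axis_move", axis=axis, target=target, feedrate=feedrate)


def tool_select(tool: int) -> MotionCommand:
    return MotionCommand("tool_select", tool=tool)


def tool_deselect() -> MotionCommand:
    return MotionCommand("tool_deselect")


def _fmt(value: float) -> str:
    return f"{value:.3f}"


def emit_gcode(command: MotionCommand) -> str:
    """Render one command as one G-code line (fixed 3-decimal coordinates)."""
    v = command.verb
    if v == "home":
        return "G28"
    if v == "tool_select":
        return f"T{command.tool}"
    if v == "tool_deselect":
        return "T-1"
    if v == "linear_move":
        parts = ["G0"]
        for letter, value in (("X", command.x), ("Y", command.y), ("Z", command.z)):
            if value is not None:
                parts.append(f"{letter}{_fmt(value)}")
        if command.feedrate is not None:
            parts.append(f"F{command.feedrate:g}")
        return " ".join(parts)
    if v == "axis_move":
        parts = ["G0", f"{command.axis}{_fmt(command.target)}"]
        if command.feedrate is not None:
            parts.append(f"F{command.feedrate:g}")
        return " ".join(parts)
    raise CommandError(f"unknown verb {v!r}")  # pragma: no cover - guarded in ctor


_WORD_RE = re.compile(r"([A-Z])(-?\d+(?:\.\d+)?)")


def parse_gcode(line: str) -> MotionCommand:
    """Parse one G-code line back into a :class:`MotionCommand`.

    Inverse of :func:`emit_gcode` for every verb (round-trip identity at
    3-decimal coordinate precision).
    """
    text = line.strip()
    if not text:
        raise CommandError("empty G-code line")
    if text == "G28":
        return home()
    m = re.fullmatch(r"T(-?\d+)", text)
    if m:
        n = int(m.group(1))
        return tool_deselect() if n == -1 else tool_select(n)
    if text.startswith("G0") or text.startswith("G1"):
        words = dict()
        for letter, number in _WORD_RE.findall(text[2:]):
            if letter in words:
                raise CommandError(f"duplicate axis word {letter!r} in {line!r}")
            words[letter] = float(number)
        feed = words.pop("F", None)
        xyz = {k: words.pop(k) for k in ("X", "Y", "Z") if k in words}
        if xyz and words:
            raise CommandError(f"mixed XYZ and auxiliary axes in {line!r}")
        if xyz:
            return linear_move(
                x=xyz.get("X"), y=xyz.get("Y"), z=xyz.get("Z"), feedrate=feed
            )
        if len(words) == 1:
            (axis, target), = words.items()
            return axis_move(axis, target, feedrate=feed)
        raise CommandError(f"cannot parse move {line!r}")
    raise CommandError(f"unrecognized G-code {line!r}")


@dataclass
class MachineState:
    """Virtual machine snapshot: position, homed flags, tools, envelope."""

    position: dict[str, float] = field(default_factory=lambda: {"X": 0.0, "Y": 0.0, "Z": 0.0})
    homed: dict[str, bool] = field(default_factory=lambda: {"X": False, "Y": False, "Z": False})
    active_tool: Optional[int] = None
    parked_tools: set[int] = field(default_factory=set)
    axis_limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_LIMITS)
    )

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.position["X"], self.position["Y"], self.position["Z"])

    def all_homed(self) -> bool:
        return all(self.homed.get(a, False) for a in ("X", "Y", "Z"))

    def in_limits(self, axis: str, value: float) -> bool:
        lo, hi = self.axis_limits.get(axis, (-math.inf, math.inf))
        return lo - 1e-9 <= value <= hi + 1e-9


@dataclass(frozen=True)
class Violation:
    """One legality-rule breach observed during virtual execution."""

    index: int
    command: MotionCommand
    message: str

    def __str__(self) -> str:
        return f"command {self.index} ({emit_gcode(self.command)}): {self.message}"


def load_machine_config(doc: dict) -> MachineState:
    """Build an initial MachineState from a machine config mapping.

    Recognized keys: ``axis_limits`` ({axis: [min, max]}), ``parked_tools``
    (list of tool ids available on the parking rail).
    """
    limits = dict(DEFAULT_AXIS_LIMITS)
    for axis, pair in doc.get("axis_limits", {}).items():
        limits[axis] = (float(pair[0]), float(pair[1]))
    state = MachineState(axis_limits=limits)
    state.parked_tools = set(doc.get("parked_tools", []))
    return state


def _execute_one(state: MachineState, idx: int, cmd: MotionCommand) -> list[Violation]:
    violations: list[Violation] = []

    def flag(msg: str) -> None:
        violations.append(Violation(idx, cmd, msg))

    if cmd.verb == "home":
        for a in state.homed:
            state.homed[a] = True
        for a in ("X", "Y", "Z"):
            lo, _ = state.axis_limits.get(a, (0.0, 0.0))
            state.position[a] = lo
    elif cmd.verb == "linear_move":
        if not state.all_homed():
            flag("unhomed move")
        for axis, value in (("X", cmd.x), ("Y", cmd.y), ("Z", cmd.z)):
            if value is None:
                continue
            if not state.in_limits(axis, value):
                lo, hi = state.axis_limits[axis]
                flag(f"{axis} target {value:.3f} outside limits [{lo:.3f}, {hi:.3f}]")
            state.position[axis] = value
    elif cmd.verb == "axis_move":
        # Auxiliary axes (syringe plunger etc.) need no XYZ homing.
        if cmd.axis in state.axis_limits and not state.in_limits(cmd.axis, cmd.target):
            lo, hi = state.axis_limits[cmd.axis]
            flag(f"{cmd.axis} target {cmd.target:.3f} outside limits [{lo:.3f}, {hi:.3f}]")
        state.position[cmd.axis] = cmd.target
    elif cmd.verb == "tool_select":
        if state.active_tool is not None and state.active_tool != cmd.tool:
            flag(f"tool change to T{cmd.tool} while T{state.active_tool} active")
        else:
            state.active_tool = cmd.tool
            state.parked_tools.discard(cmd.tool)
    elif cmd.verb == "tool_deselect":
        if state.active_tool is None:
            flag("tool deselect with no active tool")
        else:
            state.parked_tools.add(state.active_tool)
            state.active_tool = None
    return violations


def virtual_execute(
    stream: Iterable[MotionCommand],
    initial: Optional[MachineState] = None,
    strict: bool = False,
) -> tuple[MachineState, list[Violation]]:
    """Replay a command stream against the legality rules.

    Violations recorded (never raised, unless ``strict``): moving before
    homing, moving outside the axis envelope, selecting a tool while another
    is active, deselecting with no active tool.  After a legal stream the
    machine position equals the last commanded target.
    """
    state = copy.deepcopy(initial) if initial is not None else MachineState()
    violations: list[Violation] = []
    for idx, cmd in enumerate(stream):
        found = _execute_one(state, idx, cmd)
        if found and strict:
            raise MachineViolationError(str(found[0]))
        violations.extend(found)
    return state, violations


def safe_z_plan(
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    clearance_z: float = DEFAULT_CLEARANCE_Z,
    feedrate: float = 6000.0,
    axis_limits: Optional[dict[str, tuple[float, float]]] = None,
) -> list[MotionCommand]:
    """Three-move travel plan that never drops below the z clearance.

    Retract to the travel height (the clearance, or the current z if already
    higher), traverse in x/y at that height, then descend to the target z.
    The bed is lowered rather than the tool raised on the physical machine,
    but the commanded coordinates are identical.
    """
    limits = axis_limits if axis_limits is not None else DEFAULT_AXIS_LIMITS

    def check(axis: str, value: float) -> None:
        lo, hi = limits.get(axis, (-math.inf, math.inf))
        if not (lo - 1e-9 <= value <= hi + 1e-9):
            raise MachineRangeError(
                f"{axis} target {value:.3f} outside limits [{lo:.3f}, {hi:.3f}]"
            )

    travel_z = max(clearance_z, start[2])
    check("Z", clearance_z)
    check("Z", travel_z)
    for axis, value in (("X", end[0]), ("Y", end[1]), ("Z", end[2])):
        check(axis, value)
    return [
        linear_move(x=start[0], y=start[1], z=travel_z, feedrate=feedrate),
        linear_move(x=end[0], y=end[1], z=travel_z, feedrate=feedrate),
        linear_move(x=end[0], y=end[1], z=end[2], feedrate=feedrate),
    ]


class VirtualMachine:
    """Transport-contract implementation backed by :func:`virtual_execute`.

    ``send(line)`` parses and executes one G-code line, returning ``"ok"`` or
    an ``"Error: ..."`` reply, mirroring how a firmware console answers.
    """

    def __init__(self, initial: Optional[MachineState] = None, strict: bool = False):
        self.state = copy.deepcopy(initial) if initial is not None else MachineState()
        self.strict = strict
        self.violations: list[Violation] = []
        self._counter = 0

    def send(self, line: str) -> str:
        try:
            cmd = parse_gcode(line)
        except CommandError as exc:
            return f"Error: {exc}"
        found = _execute_one(self.state, self._counter, cmd)
        self._counter += 1
        if found:
            self.violations.extend(found)
            if self.strict:
                raise MachineViolationError(str(found[0]))
            return f"Error: {found[0].message}"
        return "ok"


class SerialTransport:  # pragma: no cover - requires hardware
    """Optional pyserial-backed transport for a physical machine.

    Imported lazily; construct only on a host with a connected controller.
    Implements the same ``send(line) -> reply`` contract as
    :class:`VirtualMachine`.
    """

    def __init__(self, port: str, baudrate: int = 115200, timeout: float = 10.0):
        try:
            import serial  # type: ignore
        except ImportError as exc:
            raise ImportError(
                "pyserial is required for SerialTransport; install it or use VirtualMachine"
            ) from exc
        self._conn = serial.Serial(port, baudrate=baudrate, timeout=timeout)

    def send(self, line: str) -> str:
        self._conn.write((line.strip() + "\n").encode())
        return self._conn.readline().decode().strip()
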