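"""Imaging sessions: filename convention, capture planning, deck cropping.

Well images are saved as ``<YYYY-MM-DD>_<experiment>_plate<k>_<well>.png`` —
the date, experiment name, plate and well are the filename, with underscores
as field separators (hence forbidden inside experiment names) and ISO-8601
dates, so records round-trip through parsing without ambiguity.

Two capture modes exist.  ``per_well`` visits every assigned well with the
top-down camera (highest quality, ~1 min per 24-well plate on hardware);
``whole_deck`` drops the bed and takes a single image of all plates, which
is then cropped into per-well tiles using a pixel/mm calibration.

Capture itself sits behind a minimal camera protocol (``capture(point) ->
RGB array``) so tests and simulations can bind a synthetic camera where
production binds real camera hardware.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .design import PlateLayout
from .errors import DeckError, GeometryError, NameValidationError
from .labware import DeckLayout, WellAddress, well_location

__all__ = [
    "ImagingRecord",
    "SessionPlan",
    "Capture",
    "TileSpec",
    "CameraCalibration",
    "Camera",
    "image_filename",
    "parse_image_filename",
    "plan_session",
    "crop_deck_image",
    "run_session",
]

_FILENAME_RE = re.compile(
    r"(\d{4}-\d{2}-\d{2})_([^_/\\]+)_plate(\d+)_([A-Z]\d+)\.(png|jpg|jpeg)"
)


def _check_experiment_name(name: str) -> None:
    if not name or re.search(r"[_/\\]", name):
        raise NameValidationError(
            f"experiment name {name!r} must be non-empty and contain no '_' or path separators"
        )


@dataclass(frozen=True)
class ImagingRecord:
    """Metadata of one captured well image."""

    date: Date
    experiment: str
    plate: int
    well: WellAddress
    path: Optional[Path] = None

    def filename(self, ext: str = "png") -> str:
        return image_filename(self.date, self.experiment, self.plate, self.well, ext=ext)


def image_filename(
    date: Date, experiment: str, plate: int, well, ext: str = "png"
) -> str:
    """Deterministic image file name from (date, experiment, plate, well)."""
    _check_experiment_name(experiment)
    if isinstance(well, str):
        well = WellAddress.parse(well)
    return f"{date.isoformat()}_{experiment}_plate{plate}_{well}.{ext}"


def parse_image_filename(name: str) -> ImagingRecord:
    """Invert :func:`image_filename`; accepts a bare name or a full path."""
    path = Path(name)
    m = _FILENAME_RE.fullmatch(path.name)
    if m is None:
        raise NameValidationError(f"{path.name!r} does not follow the image naming convention")
    return ImagingRecord(
        date=Date.fromisoformat(m.group(1)),
        experiment=m.group(2),
        plate=int(m.group(3)),
        well=WellAddress.parse(m.group(4)),
        path=path if str(path) != path.name else None,
    )


@dataclass(frozen=True)
class CameraCalibration:
    """Pixel/machine mapping for whole-deck cropping.

    ``px_per_mm`` scales machine mm to image pixels; ``origin_px`` is the
    pixel position of machine (0, 0); ``tile_size_px`` is the square crop
    side centred on each well.
    """

    px_per_mm: float
    origin_px: tuple[float, float] = (0.0, 0.0)
    tile_size_px: int = 128

    def to_pixel(self, point_mm: tuple[float, float]) -> tuple[float, float]:
        return (
            self.origin_px[0] + self.px_per_mm * point_mm[0],
            self.origin_px[1] + self.px_per_mm * point_mm[1],
        )


@dataclass(frozen=True)
class Capture:
    """One planned camera stop: which well, at which machine point."""

    plate: int
    well: WellAddress
    point: tuple[float, float]


@dataclass(frozen=True)
class TileSpec:
    """One crop rectangle (pixel row/col bounds) inside a whole-deck image."""

    plate: int
    well: WellAddress
    row0: int
    col0: int
    size: int


@dataclass
class SessionPlan:
    """An ordered imaging session over an experiment layout."""

    mode: str  # "per_well" | "whole_deck"
    captures: list[Capture]
    tiles: list[TileSpec]


class Camera(Protocol):
    """Anything that can take a picture at a machine point."""

    def capture(self, point: tuple[float, float]) -> np.ndarray: ...


def plan_session(
    layout: PlateLayout,
    deck: DeckLayout,
    mode: str = "per_well",
    calibration: Optional[CameraCalibration] = None,
    deck_point: tuple[float, float] = (0.0, 0.0),
) -> SessionPlan:
    """Plan captures for an experiment: one per assigned well, or one total.

    ``per_well`` lists every assigned well at its machine location, ordered
    by plate index then row-major well order.  ``whole_deck`` plans a single
    capture plus the tile map needed to crop each assigned well out of the
    full-bed image (requires a :class:`CameraCalibration`).  Pure function
    of its arguments.
    """
    if mode not in ("per_well", "whole_deck"):
        raise ValueError(f"mode must be 'per_well' or 'whole_deck', got {mode!r}")
    for p in layout.plates:
        if deck.slots[p.slot] is None:
            raise DeckError(f"plate {p.plate} expects labware in slot {p.slot}, but it is empty")

    points = [
        (plate, WellAddress.parse(well), well_location(deck, slot, WellAddress.parse(well)))
        for (plate, slot, well, _, _) in layout.assigned_wells()
    ]
    if mode == "per_well":
        captures = [Capture(plate, well, pt) for plate, well, pt in points]
        return SessionPlan(mode=mode, captures=captures, tiles=[])
    if calibration is None:
        raise ValueError("whole_deck mode requires a CameraCalibration")
    half = calibration.tile_size_px // 2
    tiles = []
    for plate, well, pt in points:
        cx, cy = calibration.to_pixel(pt)
        tiles.append(
            TileSpec(
                plate=plate,
                well=well,
                row0=int(round(cy)) - half,
                col0=int(round(cx)) - half,
                size=calibration.tile_size_px,
            )
        )
    captures = [Capture(plate=0, well=WellAddress("A", 1), point=deck_point)]
    return SessionPlan(mode=mode, captures=captures, tiles=tiles)


def crop_deck_image(
    image: np.ndarray, tiles: Sequence[TileSpec]
) -> list[tuple[TileSpec, np.ndarray]]:
    """Crop a whole-deck image into per-well tiles.

    Each returned tile is exactly the ``size`` x ``size`` sub-rectangle of
    the source (a copy), paired with its spec.  A tile extending outside the
    image raises :class:`GeometryError`.
    """
    h, w = image.shape[:2]
    out = []
    for t in tiles:
        if t.row0 < 0 or t.col0 < 0 or t.row0 + t.size > h or t.col0 + t.size > w:
            raise GeometryError(
                f"tile for plate {t.plate} well {t.well} "
                f"(rows {t.row0}:{t.row0 + t.size}, cols {t.col0}:{t.col0 + t.size}) "
                f"lies outside the {h}x{w} image"
            )
        out.append((t, image[t.row0 : t.row0 + t.size, t.col0 : t.col0 + t.size].copy()))
    return out


def run_session(
    plan: SessionPlan,
    camera: Camera,
    experiment: str,
    date: Date,
    out_dir,
) -> list[ImagingRecord]:
    """Execute a per-well session: capture each well and save named PNGs.

    Returns the imaging records (with paths) in capture order.
    """
    import imageio.v3 as iio

    if plan.mode != "per_well":
        raise ValueError("run_session executes per_well plans; crop whole-deck images instead")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for cap in plan.captures:
        image = camera.capture(cap.point)
        name = image_filename(date, experiment, cap.plate, cap.well)
        path = out / name
        iio.imwrite(path, image)
        records.append(
            ImagingRecord(date=date, experiment=experiment, plate=cap.plate, well=cap.well, path=path)
        )
    return records
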