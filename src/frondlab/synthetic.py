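"""Synthetic well images and simulated experiments with known ground truth.

No public image set exists for top-down duckweed well photography, so every
image-consuming part of the toolkit is exercised against generated data:
bright quasi-circular green fronds (saturated disks, optionally with jittered
boundaries) on a darker low-saturation well background, plus exponential
growth time series realized through the same renderer.  The generator
records the exact painted-pixel count per image, which is the cross-module
oracle the segmentation pipeline is measured against.

What this emulates: the saturation contrast between fronds and background,
frond roundness, speckle-scale lighting noise, multiplicative well-to-well
growth variability.  What it does not: photorealistic texture, specular
reflections, overlapping/overcrowded fronds, roots.  Passing tests therefore
demonstrate pipeline correctness, not field robustness on real imagery.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .design import ExperimentSpec, PlateLayout, randomize_layout, save_layout
from .errors import GeometryError
from .imaging import image_filename
from .labware import WellAddress

__all__ = [
    "FrondSpec",
    "GrowthScenario",
    "DayImage",
    "synth_well_image",
    "synth_timeseries",
    "synth_experiment",
    "fronds_for_area",
    "DEFAULT_IMAGE_SIZE",
    "FIXTURE_PIXEL_NOISE_SIGMA",
    "FIXTURE_BOUNDARY_JITTER",
]

#: Side length (px) of a square synthetic well image.
DEFAULT_IMAGE_SIZE = 160

#: Additive Gaussian pixel noise (8-bit counts) used as the fixture noise level.
FIXTURE_PIXEL_NOISE_SIGMA = 6.0

#: Relative boundary jitter amplitude used in noisy fixtures.
FIXTURE_BOUNDARY_JITTER = 0.12

_BACKGROUND_GRAY = 60    # outside the well
_WELL_GRAY = 110         # well interior (low saturation)
_FROND_VALUE = 0.78      # HSV value channel of painted fronds


@dataclass(frozen=True)
class FrondSpec:
    """One rendered frond: a green disk, optionally with a wavy boundary.

    ``hue`` is in degrees (green band around 120), ``saturation`` on the
    0-255 scale, ``jitter`` the relative boundary perturbation amplitude.
    """

    center: tuple[float, float]  # (x, y) px
    radius: float                # px
    hue: float = 120.0
    saturation: int = 200
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("frond radius must be > 0")
        if not 0 <= self.saturation <= 255:
            raise GeometryError("saturation must be in [0, 255]")
        if self.jitter < 0:
            raise GeometryError("jitter must be >= 0")


@dataclass(frozen=True)
class GrowthScenario:
    """Exponential growth of one well: area(t) = initial_area * exp(rate * t).

    ``days`` is the number of imaging sessions (t = 0 .. days-1);
    ``noise_cv`` the coefficient of variation of the mean-preserving
    multiplicative log-normal noise on the daily target area;
    ``pixel_noise_sigma`` the additive Gaussian image noise.
    """

    initial_area: float
    rate: float
    days: int
    noise_cv: float = 0.0
    pixel_noise_sigma: float = 0.0
    boundary_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_area <= 0:
            raise ValueError("initial_area must be > 0")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _frond_mask(shape: tuple[int, int], frond: FrondSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one frond as a boolean mask."""
    if frond.jitter <= 0:
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((frond.center[1], frond.center[0]), frond.radius, shape=shape)
        mask[rr, cc] = True
        return mask
    # Wavy boundary: radius modulated by a few random Fourier harmonics.
    theta = np.linspace(0, 2 * math.pi, 72, endpoint=False)
    wave = np.zeros_like(theta)
    for k in (2, 3, 5):
        wave += rng.normal(0, 1) * np.cos(k * theta) + rng.normal(0, 1) * np.sin(k * theta)
    wave /= max(np.abs(wave).max(), 1e-9)
    r = frond.radius * (1.0 + frond.jitter * wave)
    rows = frond.center[1] + r * np.sin(theta)
    cols = frond.center[0] + r * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def _frond_rgb(hue_deg: float, saturation: int) -> np.ndarray:
    rgb = hsv2rgb(np.array([[[hue_deg / 360.0, saturation / 255.0, _FROND_VALUE]]]))
    return np.round(rgb[0, 0] * 255.0).astype(np.uint8)


def synth_well_image(
    fronds: Sequence[FrondSpec],
    size: int = DEFAULT_IMAGE_SIZE,
    noise_sigma: float = 0.0,
    seed: int = 0,
    well_radius: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Render one top-down well image; returns (RGB uint8 image, truth px).

    The ground truth is the exact painted-pixel count of the union of all
    frond masks.  Deterministic under a fixed seed.  A frond reaching
    outside the well circle raises :class:`GeometryError`.
    """
    if well_radius is None:
        well_radius = size / 2.0 - 10.0
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    for f in fronds:
        d = math.hypot(f.center[0] - center[0], f.center[1] - center[1])
        if d + f.radius * (1.0 + f.jitter) > well_radius + 1e-9:
            raise GeometryError(
                f"frond at {f.center} radius {f.radius} extends outside the "
                f"well circle (radius {well_radius})"
            )
    rng = np.random.default_rng(seed)
    image = np.full((size, size, 3), _BACKGROUND_GRAY, dtype=float)
    yy, xx = np.ogrid[:size, :size]
    well = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= well_radius**2
    image[well] = _WELL_GRAY

    painted = np.zeros((size, size), dtype=bool)
    for f in fronds:
        mask = _frond_mask((size, size), f, rng)
        image[mask] = _frond_rgb(f.hue, f.saturation)
        painted |= mask
    truth = float(painted.sum())
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), truth


def fronds_for_area(
    target_area: float,
    rng: np.random.Generator,
    size: int = DEFAULT_IMAGE_SIZE,
    well_radius: Optional[float] = None,
    max_frond_radius: float = 16.0,
    jitter: float = 0.0,
) -> list[FrondSpec]:
    """Realize a target total area as one or more non-overlapping fronds.

    The area is split evenly over the fewest fronds whose individual radius
    stays at or below ``max_frond_radius``; centers are drawn uniformly
    inside the well with rejection sampling against overlap.
    """
    if well_radius is None:
        well_radius = size / 2.0 - 10.0
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    n = max(1, math.ceil(target_area / (math.pi * max_frond_radius**2)))
    radius = math.sqrt(target_area / n / math.pi)
    placed: list[tuple[float, float]] = []
    margin = radius * (1.0 + jitter) + 1.0
    reach = well_radius - margin
    if reach <= 0:
        raise GeometryError(
            f"target area {target_area:.0f} px^2 needs frond radius {radius:.1f} px, "
            f"too large for well radius {well_radius:.1f} px"
        )
    for _ in range(n):
        for _attempt in range(500):
            rho = reach * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            x = center[0] + rho * math.cos(phi)
            y = center[1] + rho * math.sin(phi)
            if all(math.hypot(x - px, y - py) >= 2 * margin for px, py in placed):
                placed.append((x, y))
                break
        else:
            # Dense case: fall back to a deterministic ring arrangement.
            placed = _ring_placement(n, center, reach, margin, rng)
            break
    return [FrondSpec(center=p, radius=radius, jitter=jitter) for p in placed]


def _ring_placement(
    n: int,
    center: tuple[float, float],
    reach: float,
    margin: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Evenly spaced fronds on the outer ring (plus one central) for crowded wells."""
    if n == 1:
        return [center]
    outer = n if 2 * reach * math.sin(math.pi / n) >= 2 * margin else n - 1
    if outer < 2 or 2 * reach * math.sin(math.pi / outer) < 2 * margin:
        raise GeometryError(
            f"cannot arrange {n} fronds of effective radius {margin:.1f} px "
            f"inside placement radius {reach:.1f} px"
        )
    if outer == n - 1 and reach < 2 * margin:
        raise GeometryError(
            f"cannot arrange {n} fronds of effective radius {margin:.1f} px "
            f"inside placement radius {reach:.1f} px"
        )
    phase = rng.uniform(0, 2 * math.pi)
    points = [
        (
            center[0] + reach * math.cos(phase + 2 * math.pi * k / outer),
            center[1] + reach * math.sin(phase + 2 * math.pi * k / outer),
        )
        for k in range(outer)
    ]
    if outer == n - 1:
        points.append(center)
    return points


@dataclass
class DayImage:
    """One day of a synthetic time series."""

    day: int
    image: np.ndarray
    truth_area: float   # exact painted-pixel count
    target_area: float  # noisy exponential target the renderer aimed for
    clipped: bool


def synth_timeseries(
    scenario: GrowthScenario,
    size: int = DEFAULT_IMAGE_SIZE,
    well_radius: Optional[float] = None,
) -> list[DayImage]:
    """Render a dated image sequence following exponential growth.

    The day-t target area is ``initial_area * exp(rate * t)`` perturbed by
    mean-preserving multiplicative log-normal noise of the stated cv.
    Targets exceeding the well's renderable capacity are clipped, flagged,
    and reported with a warning.
    """
    if well_radius is None:
        well_radius = size / 2.0 - 10.0
    capacity = 0.30 * math.pi * well_radius**2
    sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2)) if scenario.noise_cv > 0 else 0.0
    out: list[DayImage] = []
    for day in range(scenario.days):
        rng = np.random.default_rng([scenario.seed, day])
        target = scenario.initial_area * math.exp(scenario.rate * day)
        if sigma > 0:
            target *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        clipped = target > capacity
        if clipped:
            warnings.warn(
                f"day {day}: target area {target:.0f} px^2 exceeds well capacity "
                f"{capacity:.0f} px^2; clipping",
                stacklevel=2,
            )
            target = capacity
        fronds = fronds_for_area(
            target, rng, size=size, well_radius=well_radius, jitter=scenario.boundary_jitter
        )
        image, truth = synth_well_image(
            fronds,
            size=size,
            noise_sigma=scenario.pixel_noise_sigma,
            seed=int(rng.integers(0, 2**31)),
            well_radius=well_radius,
        )
        out.append(DayImage(day=day, image=image, truth_area=truth, target_area=target, clipped=clipped))
    return out


def synth_experiment(
    spec: ExperimentSpec,
    days: int,
    out_dir,
    seed: int = 0,
    scenarios: Optional[dict[tuple[str, str], GrowthScenario]] = None,
    initial_area: float = 300.0,
    rate: float = 0.30,
    noise_cv: float = 0.05,
    pixel_noise_sigma: float = FIXTURE_PIXEL_NOISE_SIGMA,
    boundary_jitter: float = FIXTURE_BOUNDARY_JITTER,
    start_date: Date = Date(2026, 1, 1),
    size: int = DEFAULT_IMAGE_SIZE,
) -> tuple[Path, PlateLayout, pd.DataFrame]:
    """Simulate a full growth assay: layout JSON, image tree, ground truth.

    Randomizes the layout from ``spec``, writes the experiment directory,
    then renders one image per assigned well per day with per-well
    exponential growth.  ``scenarios`` may override the growth parameters
    per (genotype, media) condition; otherwise every condition uses the
    module-level defaults.  The produced directory is a drop-in input for
    :func:`frondlab.quantify.analyze_experiment`.

    Returns (experiment dir, layout, ground-truth table) where the table has
    one row per image with the exact painted area.
    """
    layout = randomize_layout(spec)
    base = save_layout(layout, out_dir)
    images_dir = base / "images"
    rows = []
    for (plate, slot, well, genotype, media) in layout.assigned_wells():
        if scenarios is not None and (genotype, media) in scenarios:
            template = scenarios[(genotype, media)]
            template = replace(template, days=days)
        else:
            template = GrowthScenario(
                initial_area=initial_area,
                rate=rate,
                days=days,
                noise_cv=noise_cv,
                pixel_noise_sigma=pixel_noise_sigma,
                boundary_jitter=boundary_jitter,
            )
        addr = WellAddress.parse(well)
        well_seed = int(
            np.random.SeedSequence(
                [seed, plate, addr.row_index, addr.column]
            ).generate_state(1)[0]
            % 2**31
        )
        series = synth_timeseries(replace(template, seed=well_seed), size=size)
        for entry in series:
            d = start_date + timedelta(days=entry.day)
            name = image_filename(d, spec.name, plate, well)
            _write_png(images_dir / name, entry.image)
            rows.append(
                {
                    "date": d,
                    "day": entry.day,
                    "plate": plate,
                    "well": well,
                    "genotype": genotype,
                    "media": media,
                    "truth_area": entry.truth_area,
                    "target_area": entry.target_area,
                    "clipped": entry.clipped,
                }
            )
    truth = pd.DataFrame(rows)
    truth.to_csv(base / "ground_truth.csv", index=False)
    return base, layout, truth


def _write_png(path: Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, image)
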