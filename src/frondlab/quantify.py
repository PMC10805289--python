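"""Frond-area quantification from top-down well images.

The pipeline is deliberately simple and avoids per-species green-pixel
tuning: convert RGB to HSV, binarize the saturation channel (vivid fronds
against a gray well background), restrict to a circular well mask that
excludes wall reflections, extract connected regions, and drop regions that
are too small or not round enough to be fronds.  Total frond area in pixels
is the growth readout; a well with no surviving region counts as empty,
which is also how transfer success is verified.

The saturation threshold depends on lighting and must be set once per rig;
the default (80 of 255) is a fixture value.  Roundness is the normalized
circularity 4*pi*A/P^2 (1 for a disk, scale-invariant); the raw
perimeter-to-area ratio is available behind ``use_perimeter_area_ratio``
for users who prefer the scale-dependent variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.color import rgb2hsv

from .design import PlateLayout
from .errors import ImageFormatError, LayoutLookupError
from .imaging import ImagingRecord, parse_image_filename

__all__ = [
    "SegmentationParams",
    "ContourStats",
    "WellMeasurement",
    "SegmentationResult",
    "segment_fronds",
    "total_frond_area",
    "is_well_empty",
    "measure_well",
    "growth_curves",
    "fit_growth_rates",
    "analyze_experiment",
    "plot_growth_curves",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the frond segmentation pipeline.

    saturation_threshold : int
        Binarization level on the 0-255 saturation channel; rig-specific.
    min_contour_area : float
        Regions smaller than this (px^2) are lighting speckle, not fronds.
    roundness_min : float
        Minimum circularity 4*pi*A/P^2 for a kept region, in (0, 1].
    well_mask_margin : int
        Pixels shaved off the inscribed well circle to exclude wall glare.
    use_perimeter_area_ratio : bool
        If set, filter on raw P/A <= perimeter_area_max instead of
        circularity.
    """

    saturation_threshold: int = 80
    min_contour_area: float = 50.0
    roundness_min: float = 0.60
    well_mask_margin: int = 6
    use_perimeter_area_ratio: bool = False
    perimeter_area_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.saturation_threshold <= 255:
            raise ValueError("saturation_threshold must be in [0, 255]")
        if not 0 < self.roundness_min <= 1.0:
            raise ValueError("roundness_min must be in (0, 1]")
        if self.min_contour_area < 0 or self.well_mask_margin < 0:
            raise ValueError("min_contour_area and well_mask_margin must be >= 0")


@dataclass(frozen=True)
class ContourStats:
    """Measurements of one connected region candidate."""

    area: float          # px^2 (pixel count)
    perimeter: float     # px
    roundness: float     # 4*pi*A/P^2; 1 for a disk
    centroid: tuple[float, float]  # (x, y) px


@dataclass
class SegmentationResult:
    mask: np.ndarray                 # boolean frond mask (inside well circle)
    kept: list[ContourStats]
    rejected: list[ContourStats]


@dataclass
class WellMeasurement:
    """One well on one day: total frond area and QC counts."""

    record: Optional[ImagingRecord]
    total_frond_area: float
    n_contours_kept: int
    n_contours_rejected: int


def _well_circle_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    h, w = shape
    radius = min(h, w) / 2.0 - margin
    yy, xx = np.ogrid[:h, :w]
    return (xx - (w - 1) / 2.0) ** 2 + (yy - (h - 1) / 2.0) ** 2 <= radius**2


def segment_fronds(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> SegmentationResult:
    """Segment fronds in one RGB well image.

    Thresholds the HSV saturation channel inside the circular well mask,
    labels connected regions, and partitions them exhaustively into kept
    (area and roundness pass) and rejected.
    """
    if not (isinstance(image, np.ndarray) and image.ndim == 3 and image.shape[2] == 3):
        raise ImageFormatError(
            f"expected an RGB image of shape (h, w, 3), got {getattr(image, 'shape', None)}"
        )
    saturation = rgb2hsv(image)[..., 1] * 255.0
    mask = (saturation >= params.saturation_threshold) & _well_circle_mask(
        image.shape[:2], params.well_mask_margin
    )
    labels = measure.label(mask, connectivity=2)
    kept: list[ContourStats] = []
    rejected: list[ContourStats] = []
    for region in measure.regionprops(labels):
        area = float(region.area)
        perimeter = float(region.perimeter)
        roundness = 1.0 if perimeter <= 0 else 4.0 * math.pi * area / perimeter**2
        cy, cx = region.centroid
        stats = ContourStats(area=area, perimeter=perimeter, roundness=roundness, centroid=(cx, cy))
        if params.use_perimeter_area_ratio:
            shape_ok = perimeter / area <= params.perimeter_area_max if area > 0 else False
        else:
            shape_ok = roundness >= params.roundness_min
        if area >= params.min_contour_area and shape_ok:
            kept.append(stats)
        else:
            rejected.append(stats)
    return SegmentationResult(mask=mask, kept=kept, rejected=rejected)


def total_frond_area(kept: Sequence[ContourStats]) -> float:
    """Sum of kept region areas in px^2 (0 for an empty list)."""
    return float(sum(c.area for c in kept))


def is_well_empty(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> bool:
    """True iff no region survives the area and shape filters."""
    return not segment_fronds(image, params).kept


def measure_well(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    record: Optional[ImagingRecord] = None,
) -> WellMeasurement:
    result = segment_fronds(image, params)
    return WellMeasurement(
        record=record,
        total_frond_area=total_frond_area(result.kept),
        n_contours_kept=len(result.kept),
        n_contours_rejected=len(result.rejected),
    )


def growth_curves(measurements: Sequence[WellMeasurement], layout: PlateLayout) -> pd.DataFrame:
    """Aggregate per-well areas into per-(genotype, media) daily curves.

    Each row is one condition on one day: replicate mean area, standard
    deviation and replicate count.  Wells missing on a day are simply
    absent, never zero-filled.  A measurement from a well the layout does
    not assign raises :class:`LayoutLookupError`.
    """
    rows = []
    for m in measurements:
        if m.record is None:
            raise LayoutLookupError("growth_curves needs measurements with imaging records")
        genotype, media = layout.condition_of(m.record.plate, str(m.record.well))
        rows.append(
            {
                "date": m.record.date,
                "plate": m.record.plate,
                "well": str(m.record.well),
                "genotype": genotype,
                "media": media,
                "area": m.total_frond_area,
            }
        )
    per_well = pd.DataFrame(rows)
    day0 = per_well["date"].min()
    per_well["day"] = per_well["date"].map(lambda d: (d - day0).days)
    curves = (
        per_well.groupby(["genotype", "media", "day"], as_index=False)
        .agg(mean_area=("area", "mean"), sd_area=("area", "std"), n=("area", "size"))
        .sort_values(["genotype", "media", "day"], ignore_index=True)
    )
    curves["sd_area"] = curves["sd_area"].fillna(0.0)
    return curves


def fit_growth_rates(curves: pd.DataFrame) -> pd.DataFrame:
    """Per-condition exponential growth rate by log-linear least squares.

    Fits log(mean area) against day for each (genotype, media); the slope is
    the relative growth rate per day.  Days with non-positive mean area are
    dropped from the fit; conditions with fewer than two usable days get NaN.
    """
    out = []
    for (genotype, media), grp in curves.groupby(["genotype", "media"]):
        grp = grp[grp["mean_area"] > 0]
        if len(grp) < 2:
            rate, intercept = float("nan"), float("nan")
        else:
            rate, intercept = np.polyfit(grp["day"].to_numpy(float), np.log(grp["mean_area"].to_numpy(float)), 1)
        out.append(
            {
                "genotype": genotype,
                "media": media,
                "rate_per_day": float(rate),
                "initial_area": float(np.exp(intercept)),
                "n_days": int(len(grp)),
            }
        )
    return pd.DataFrame(out)


def analyze_experiment(
    experiment_dir,
    params: SegmentationParams = SegmentationParams(),
    write: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full analysis over an experiment directory tree.

    Reads the layout JSON and every image under ``images/`` (named by the
    imaging convention), measures frond area per well, aggregates growth
    curves and fits per-condition rates.  When ``write`` is set, results are
    saved as CSVs under ``results/`` together with a growth-curve figure.

    Returns (per-well measurements, curves, rates) as DataFrames.
    """
    import imageio.v3 as iio

    from .design import load_layout

    base = Path(experiment_dir)
    layout = load_layout(base)
    measurements = []
    for path in sorted((base / "images").glob("*.png")):
        record = parse_image_filename(path)
        image = np.asarray(iio.imread(path))[..., :3]
        measurements.append(measure_well(image, params, record=record))
    if not measurements:
        raise FileNotFoundError(f"no images found under {base / 'images'}")
    per_well = pd.DataFrame(
        {
            "date": [m.record.date for m in measurements],
            "plate": [m.record.plate for m in measurements],
            "well": [str(m.record.well) for m in measurements],
            "total_frond_area": [m.total_frond_area for m in measurements],
            "n_contours_kept": [m.n_contours_kept for m in measurements],
            "n_contours_rejected": [m.n_contours_rejected for m in measurements],
        }
    )
    curves = growth_curves(measurements, layout)
    rates = fit_growth_rates(curves)
    if write:
        results = base / "results"
        results.mkdir(exist_ok=True)
        per_well.to_csv(results / "well_measurements.csv", index=False)
        curves.to_csv(results / "growth_curves.csv", index=False)
        rates.to_csv(results / "growth_rates.csv", index=False)
        plot_growth_curves(curves, results / "growth_curves.png")
    return per_well, curves, rates


def plot_growth_curves(curves: pd.DataFrame, path=None):
    """One panel per genotype, one line per media: mean area +/- sd over days."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genotypes = sorted(curves["genotype"].unique())
    fig, axes = plt.subplots(1, len(genotypes), figsize=(4 * len(genotypes), 3.2), squeeze=False)
    for ax, genotype in zip(axes[0], genotypes):
        sub = curves[curves["genotype"] == genotype]
        for media, grp in sub.groupby("media"):
            ax.errorbar(grp["day"], grp["mean_area"], yerr=grp["sd_area"], label=media, marker="o", capsize=2)
        ax.set_title(genotype)
        ax.set_xlabel("day")
        ax.set_ylabel("frond area (px)")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
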