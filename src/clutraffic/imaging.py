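"""Per-cell quantification of reporter distribution.

Given a registered multi-channel field and manually delineated cell regions,
each cell is scored by (i) the background-corrected Golgi enrichment ratio —
mean reporter intensity inside an automatically segmented Golgi region
divided by the mean over the rest of the cell — and (ii) the Pearson
correlation between the reporter and the ER-marker channel.  Cells whose
background-corrected mean reporter signal outside the Golgi falls below a
fixed cutoff are flagged as low-expressing and excluded from group
statistics.

The Golgi is segmented on the Golgi-*marker* channel (Otsu threshold within
the cell region, then removal of connected components below a minimum pixel
size); thresholding the reporter itself would leave ER-retained mutants with
no Golgi region to measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .exceptions import CoverageError, DegenerateThresholdError, ParameterError
from .scenes import SyntheticScene

__all__ = [
    "GolgiSegmentation",
    "CellMeasurement",
    "QuantConfig",
    "estimate_background",
    "segment_golgi",
    "golgi_enrichment_ratio",
    "exclude_low_signal",
    "pearson_colocalization",
    "quantify_image",
    "measurements_to_frame",
]

CELL_CSV_COLUMNS = [
    "image_id",
    "cell_id",
    "genotype",
    "golgi_ratio",
    "mean_outside",
    "pearson_er",
    "excluded",
]


@dataclass(frozen=True)
class GolgiSegmentation:
    mask: np.ndarray
    threshold_value: float
    min_object_px: int


@dataclass(frozen=True)
class CellMeasurement:
    """One cell's scores; NaN marks a measurement that was undefined."""

    cell_id: int
    genotype: str
    golgi_ratio: float
    mean_outside: float
    pearson_er: float
    excluded: bool = False
    image_id: str = ""


@dataclass(frozen=True)
class QuantConfig:
    """Analysis knobs for batch quantification.

    ``cutoff`` is the fixed low-signal exclusion threshold on the
    background-corrected mean reporter intensity outside the Golgi; the
    default ``None`` resolves to background mean + ``cutoff_sd_factor`` ×
    background sd of the reporter channel.
    """

    min_object_px: int = 20
    cutoff: float | None = None
    cutoff_sd_factor: float = 2.0
    min_background_px: int = 100


def estimate_background(image_channel: np.ndarray, all_cell_rois) -> tuple[float, float]:
    """Mean and sd of a channel over pixels belonging to no cell region."""
    image_channel = np.asarray(image_channel, dtype=float)
    outside = np.ones(image_channel.shape, dtype=bool)
    for roi in all_cell_rois:
        outside &= ~np.asarray(roi, dtype=bool)
    n = int(outside.sum())
    if n < 100:
        raise CoverageError(
            f"only {n} pixels outside all cell regions; need at least 100"
        )
    vals = image_channel[outside]
    return float(vals.mean()), float(vals.std(ddof=1))


def segment_golgi(
    golgi_channel: np.ndarray,
    cell_roi: np.ndarray,
    min_object_px: int = 20,
    connectivity: int = 2,
) -> GolgiSegmentation:
    """Otsu threshold within the cell region, then size-filter the mask."""
    cell_roi = np.asarray(cell_roi, dtype=bool)
    if not cell_roi.any():
        raise ParameterError("cell_roi is empty")
    vals = np.asarray(golgi_channel, dtype=float)[cell_roi]
    if np.ptp(vals) == 0:
        raise DegenerateThresholdError(
            "Golgi channel constant inside the cell region; Otsu undefined"
        )
    thr = float(threshold_otsu(vals))
    mask = (np.asarray(golgi_channel, dtype=float) > thr) & cell_roi
    if min_object_px > 1:
        # components strictly smaller than min_object_px are removed
        mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=connectivity)
    return GolgiSegmentation(mask=mask, threshold_value=thr, min_object_px=min_object_px)


def golgi_enrichment_ratio(
    reporter_channel: np.ndarray,
    cell_roi: np.ndarray,
    golgi_mask: np.ndarray,
    background_mean: float,
) -> tuple[float, float]:
    """Background-corrected in/out Golgi intensity ratio for one cell.

    Returns ``(ratio, mean_outside)`` where ``ratio = (mean_in − bg) /
    (mean_out − bg)`` and ``mean_outside = mean_out − bg`` feeds the
    low-signal exclusion rule.  The ratio is NaN when the Golgi mask is
    empty or the corrected outside mean is non-positive; the cell is still
    recorded.
    """
    reporter = np.asarray(reporter_channel, dtype=float)
    cell_roi = np.asarray(cell_roi, dtype=bool)
    golgi_mask = np.asarray(golgi_mask, dtype=bool)
    if (golgi_mask & ~cell_roi).any():
        raise ParameterError("golgi_mask extends outside the cell region")
    outside = cell_roi & ~golgi_mask
    if not outside.any():
        raise ParameterError("cell region minus Golgi mask is empty")
    mean_out = float(reporter[outside].mean()) - background_mean
    if not golgi_mask.any():
        return math.nan, mean_out
    mean_in = float(reporter[golgi_mask].mean()) - background_mean
    if mean_out <= 0:
        return math.nan, mean_out
    return mean_in / mean_out, mean_out


def exclude_low_signal(
    measurements: list[CellMeasurement], cutoff: float
) -> list[CellMeasurement]:
    """Flag cells whose corrected mean signal outside the Golgi is below
    ``cutoff``; order preserved, no records dropped."""
    if cutoff < 0:
        raise ParameterError(f"cutoff must be >= 0, got {cutoff}")
    return [
        replace(m, excluded=bool(m.mean_outside < cutoff)) for m in measurements
    ]


def pearson_colocalization(
    channel_a: np.ndarray, channel_b: np.ndarray, cell_roi: np.ndarray
) -> float:
    """Sample Pearson correlation of two channels over the cell's pixels.

    All pixels in the region enter the correlation (no Costes-style
    intensity thresholding).  NaN when fewer than two pixels or a constant
    channel makes the correlation undefined.
    """
    roi = np.asarray(cell_roi, dtype=bool)
    a = np.asarray(channel_a, dtype=float)[roi]
    b = np.asarray(channel_b, dtype=float)[roi]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(stats.pearsonr(a, b).statistic)


def quantify_image(
    scene: SyntheticScene | None = None,
    channels: dict[str, np.ndarray] | None = None,
    cell_rois: dict[int, np.ndarray] | None = None,
    genotype_by_cell: dict[int, str] | None = None,
    config: QuantConfig | None = None,
    image_id: str = "",
) -> list[CellMeasurement]:
    """Run the per-cell measurement battery over one field.

    Accepts either a :class:`SyntheticScene` (truth cell masks serve as the
    delineated regions) or explicit ``channels`` + ``cell_rois``.  Per-cell
    failures (empty Golgi mask, degenerate denominator, constant channel)
    become NaN entries; the batch never aborts on a single cell.
    """
    config = config or QuantConfig()
    if scene is not None:
        channels = scene.channels
        cell_rois = {cid: scene.cell_mask(cid) for cid in scene.cell_ids}
        genotype_by_cell = scene.phenotype_by_cell
    if channels is None or cell_rois is None:
        raise ParameterError("provide a scene or channels plus cell_rois")
    genotype_by_cell = genotype_by_cell or {}
    if not cell_rois:
        return []

    shapes = {ch.shape for ch in channels.values()}
    if len(shapes) != 1:
        raise ParameterError(f"channel shapes differ: {shapes}")

    rois = list(cell_rois.values())
    bg_mean, bg_sd = estimate_background(channels["reporter"], rois)
    if config.cutoff is None:
        cutoff = max(bg_mean + config.cutoff_sd_factor * bg_sd, 0.0)
    else:
        cutoff = config.cutoff

    measurements: list[CellMeasurement] = []
    for cell_id in sorted(cell_rois):
        roi = np.asarray(cell_rois[cell_id], dtype=bool)
        genotype = genotype_by_cell.get(cell_id, "")
        try:
            seg = segment_golgi(channels["golgi"], roi, config.min_object_px)
            golgi_mask = seg.mask
        except DegenerateThresholdError:
            golgi_mask = np.zeros_like(roi)
        ratio, mean_outside = golgi_enrichment_ratio(
            channels["reporter"], roi, golgi_mask, bg_mean
        )
        pearson = pearson_colocalization(channels["reporter"], channels["er"], roi)
        measurements.append(
            CellMeasurement(
                cell_id=cell_id,
                genotype=genotype,
                golgi_ratio=ratio,
                mean_outside=mean_outside,
                pearson_er=pearson,
                image_id=image_id,
            )
        )
    return exclude_low_signal(measurements, cutoff)


def measurements_to_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Per-cell table in the pipeline's CSV schema."""
    return pd.DataFrame(
        [
            {
                "image_id": m.image_id,
                "cell_id": m.cell_id,
                "genotype": m.genotype,
                "golgi_ratio": m.golgi_ratio,
                "mean_outside": m.mean_outside,
                "pearson_er": m.pearson_er,
                "excluded": m.excluded,
            }
            for m in measurements
        ],
        columns=CELL_CSV_COLUMNS,
    )
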