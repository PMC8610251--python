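"""Intensity-ratio and puncta statistics.

Covers the membrane-recruitment F_H/F_L line-profile ratio, organelle-
to-cytosol intensity ratios through a reference-channel mask, background-
corrected mean probe intensity per cell, area-gated puncta counting, and
puncta-on-lysosome association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import profile_line

from .core import CellRegion

#: default puncta area gate in μm², as published for galectin-3 puncta;
#: exposed because the appropriate bounds depend on acquisition scale.
DEFAULT_PUNCTA_GATE_UM2 = (50.0, 1000.0)

#: default centroid-to-boundary distance (μm) below which a punctum
#: counts as lysosome-associated (≈ 2–3 pixels at 0.1 μm/pixel).
DEFAULT_ASSOCIATION_DISTANCE_UM = 0.25

_STRUCT_8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# line-profile membrane-recruitment ratio
# ---------------------------------------------------------------------------

@dataclass
class LineProfile:
    """A width-averaged intensity profile along a 3-pixel-wide line.

    ``values`` hold the across-width mean at each sampled point; valid
    profiles are 20–40 samples long.
    """

    start: tuple[float, float]       # (row, col) pixels
    end: tuple[float, float]
    values: np.ndarray
    width: int = 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not 20 <= len(self.values) <= 40:
            raise ValueError(
                f"profile length must be 20–40 samples, got {len(self.values)}")


@dataclass
class RatioResult:
    """One dimensionless intensity-ratio measurement for one cell.

    ``value`` is ``None`` when the measurement could not be made (e.g.
    an empty reference mask); that is a flagged no-value result, not 0.
    """

    cell_id: str
    metric_name: str
    value: float | None
    background_used: float = 0.0


def extract_line_profile(image: np.ndarray, start: tuple[float, float],
                         end: tuple[float, float], width: int = 3) -> LineProfile:
    """Sample a width-averaged straight-line profile from an image.

    Averaging across the line width precedes any sorting done by the
    ratio statistic.  Coordinates are (row, col) pixel positions.
    """
    values = profile_line(np.asarray(image, dtype=float), start, end,
                          linewidth=width, reduce_func=np.mean, mode="constant")
    return LineProfile(start=start, end=end, values=values, width=width)


def line_profile_ratio(profile: LineProfile | np.ndarray) -> float:
    """F_H/F_L: mean of the 10 highest over the 10 lowest profile values.

    Values ≈ 1 indicate a cytosolic (uniform) distribution; values > 1
    indicate punctate/membrane-localized signal.  The ratio is ≥ 1 by
    construction.  A non-positive F_L (over-subtracted background) is an
    error rather than being clamped.
    """
    values = profile.values if isinstance(profile, LineProfile) else \
        np.asarray(profile, dtype=float)
    if len(values) < 20:
        raise ValueError("need at least 20 profile values")
    ordered = np.sort(values)[::-1]
    f_high = float(ordered[:10].mean())
    f_low = float(ordered[-10:].mean())
    if f_low <= 0:
        raise ValueError("F_L is non-positive; check background subtraction")
    return f_high / f_low


def grid_line_profiles(image: np.ndarray, cell: CellRegion, k: int,
                       seed: int, length_px: int = 30, width: int = 3
                       ) -> list[LineProfile]:
    """Deterministic unbiased line placement on a fixed 4×4 anchor grid.

    Candidate horizontal lines of ``length_px`` are centered on a 4×4
    grid over the cell bounding box; lines leaving the cell mask or
    overlapping the nucleus are discarded, and ``k`` of the survivors are
    chosen with a seeded generator — a deterministic stand-in for blinded
    manual placement.
    """
    rows = np.any(cell.mask, axis=1).nonzero()[0]
    cols = np.any(cell.mask, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    anchors = [(r0 + (i + 0.5) * (r1 - r0) / 4, c0 + (j + 0.5) * (c1 - c0) / 4)
               for i in range(4) for j in range(4)]
    candidates = []
    half = length_px / 2
    for (ar, ac) in anchors:
        start = (ar, ac - half)
        end = (ar, ac + half)
        rr = int(round(ar))
        cc0, cc1 = int(np.floor(start[1])), int(np.ceil(end[1]))
        if cc0 < 0 or cc1 >= cell.mask.shape[1] or not (0 <= rr < cell.mask.shape[0]):
            continue
        span = cell.mask[rr, cc0:cc1 + 1]
        if not span.all():
            continue
        if cell.nucleus_mask is not None and cell.nucleus_mask[rr, cc0:cc1 + 1].any():
            continue
        candidates.append((start, end))
    rng = np.random.default_rng(seed)
    if k > len(candidates):
        raise ValueError(f"only {len(candidates)} candidate lines available")
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return [extract_line_profile(image, *candidates[i], width=width)
            for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# mask-based ratios and per-cell means
# ---------------------------------------------------------------------------

def reference_mask(reference: np.ndarray, cell: CellRegion,
                   factor: float = 2.0) -> np.ndarray:
    """Threshold the reference channel at factor × mean cytosol intensity."""
    reference = np.asarray(reference, dtype=float)
    if cell.cytosol_sample is None:
        raise ValueError("cell has no cytosol sample for thresholding")
    thr = factor * reference[cell.cytosol_sample].mean()
    return (reference > thr) & cell.mask


def organelle_to_cytosol_ratio(marker: np.ndarray, reference: np.ndarray,
                               cell: CellRegion, background_mask: np.ndarray,
                               metric_name: str = "organelle_to_cytosol",
                               factor: float = 2.0) -> RatioResult:
    """Ratio of marker intensity on the reference-defined organelle mask
    to marker intensity in the remaining cytosol, both background-
    corrected.

    The reference channel (e.g. dextran marking lysosomes) is
    thresholded at 2× its cytosolic mean to build the organelle mask;
    the marker channel (e.g. clathrin-eGFP, Fluo-4, LC3 GFP/mCherry) is
    then averaged over the mask and over the cytosol excluding the mask,
    after subtracting the mean extracellular background.  An empty
    reference mask yields a flagged no-value result.
    """
    marker = np.asarray(marker, dtype=float)
    mask = reference_mask(reference, cell, factor)
    background = float(marker[np.asarray(background_mask, bool)].mean())
    if not mask.any():
        return RatioResult(cell.cell_id, metric_name, None, background)
    cytosol = cell.mask & ~mask
    if cell.nucleus_mask is not None:
        cytosol &= ~cell.nucleus_mask
    numerator = marker[mask].mean() - background
    denominator = marker[cytosol].mean() - background
    if denominator == 0:
        return RatioResult(cell.cell_id, metric_name, None, background)
    return RatioResult(cell.cell_id, metric_name,
                       float(numerator / denominator), background)


def mean_cell_intensity(image: np.ndarray, cell: CellRegion,
                        background_mask: np.ndarray) -> float:
    """Background-corrected mean fluorescence intensity per cell."""
    image = np.asarray(image, dtype=float)
    background = image[np.asarray(background_mask, bool)].mean()
    return float(image[cell.mask].mean() - background)


# ---------------------------------------------------------------------------
# puncta counting and association
# ---------------------------------------------------------------------------

@dataclass
class Punctum:
    centroid: tuple[float, float]    # (x, y) μm
    area: float                      # μm²
    mean_intensity: float


@dataclass
class PunctaSet:
    """Area-gated puncta for one cell."""

    cell_id: str
    puncta: list[Punctum] = field(default_factory=list)
    gate: tuple[float, float] = DEFAULT_PUNCTA_GATE_UM2

    @property
    def count(self) -> int:
        return len(self.puncta)


def _resolve_threshold(image: np.ndarray, cell: CellRegion, policy) -> float:
    if policy == "otsu":
        return float(threshold_otsu(image[cell.mask]))
    if policy == "cytosol":
        if cell.cytosol_sample is None:
            raise ValueError("cytosol policy needs a cytosol sample")
        return float(2.0 * image[cell.cytosol_sample].mean())
    return float(policy)


def count_puncta(image: np.ndarray, cell: CellRegion, pixel_size: float,
                 threshold="otsu",
                 gate: tuple[float, float] = DEFAULT_PUNCTA_GATE_UM2) -> PunctaSet:
    """Count supra-threshold puncta whose area falls inside the gate.

    The threshold is computed per cell (``"otsu"`` on in-cell pixels,
    ``"cytosol"`` for the 2×-cytosol policy, or a fixed value);
    8-connected components inside the cell with area within
    ``[gate[0], gate[1]]`` μm² are retained — smaller particles are
    treated as noise, larger ones as non-punctate signal.
    """
    image = np.asarray(image, dtype=float)
    thr = _resolve_threshold(image, cell, threshold)
    mask = (image > thr) & cell.mask
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    puncta: list[Punctum] = []
    if n:
        areas = ndimage.sum_labels(np.ones(mask.shape), labels,
                                   index=range(1, n + 1)) * pixel_size ** 2
        coms = ndimage.center_of_mass(image, labels, index=range(1, n + 1))
        means = ndimage.mean(image, labels, index=range(1, n + 1))
        for area, (cy, cx), mean in zip(areas, coms, means):
            if gate[0] <= area <= gate[1]:
                puncta.append(Punctum(
                    centroid=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
                    area=float(area), mean_intensity=float(mean)))
    return PunctaSet(cell_id=cell.cell_id, puncta=puncta, gate=gate)


def lysosome_mask_2d(image: np.ndarray, cell: CellRegion,
                     factor: float = 2.0) -> np.ndarray:
    """2D lysosome segmentation by the 2×-cytosol threshold doctrine."""
    return reference_mask(np.asarray(image, dtype=float), cell, factor)


def lysosome_associated_puncta(
        puncta: PunctaSet, lysosome_mask: np.ndarray, pixel_size: float,
        association_distance: float = DEFAULT_ASSOCIATION_DISTANCE_UM) -> int:
    """Count puncta whose centroid lies within ``association_distance``
    μm of (or inside) any lysosome segment.

    Association uses the Euclidean distance transform of the lysosome
    background, so a centroid inside a lysosome is associated at any
    distance ≥ 0.
    """
    lysosome_mask = np.asarray(lysosome_mask, dtype=bool)
    if not lysosome_mask.any():
        return 0
    dist = ndimage.distance_transform_edt(~lysosome_mask,
                                          sampling=(pixel_size, pixel_size))
    count = 0
    for punctum in puncta.puncta:
        col = int(punctum.centroid[0] / pixel_size)
        row = int(punctum.centroid[1] / pixel_size)
        row = np.clip(row, 0, dist.shape[0] - 1)
        col = np.clip(col, 0, dist.shape[1] - 1)
        if dist[row, col] <= association_distance:
            count += 1
    return count
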