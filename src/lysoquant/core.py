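"""Shared data containers and file I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` for 3D stacks and ``(y, x)`` for 2D
  images; multi-channel data carry a leading channel axis.
* Physical coordinates are expressed in micrometres with the origin at the
  image corner.  A pixel/voxel with index ``i`` along an axis of spacing
  ``s`` has its *center* at ``(i + 0.5) * s``.  This removes the half-pixel
  ambiguity when comparing recovered positions against ground truth.
* Voxel sizes are given as ``(size_x, size_y, size_z)`` in μm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VolumetricImage:
    """One channel of a 3D fluorescence stack with physical voxel sizes.

    Parameters
    ----------
    intensities : ndarray, shape (z, y, x)
        Non-negative intensity values.
    voxel_size : tuple of float
        ``(x, y, z)`` voxel edge lengths in μm.
    channel_name : str
        Free-text channel label (e.g. ``"lucifer_yellow"``).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        if min(self.intensities.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (x, y, z)")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        sx, sy, sz = self.voxel_size
        return sx * sy * sz


@dataclass
class CellRegion:
    """A per-cell region of interest.

    ``mask`` may be 2D (applied to every z-plane) or 3D.  ``cytosol_sample``
    is the sub-region used to estimate mean cytosolic fluorescence: the cell
    mask with segmented organelles (and, where defined, the nucleus)
    excluded.  It must be contained in ``mask``.
    """

    cell_id: str
    mask: np.ndarray
    cytosol_sample: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"cell {self.cell_id!r}: mask is empty")
        if self.cytosol_sample is not None:
            self.cytosol_sample = np.asarray(self.cytosol_sample, dtype=bool)
            if self.cytosol_sample.shape != self.mask.shape:
                raise ValueError("cytosol_sample shape must match mask")
            if np.any(self.cytosol_sample & ~self.mask):
                raise ValueError("cytosol_sample must be contained in mask")

    def mask_3d(self, n_planes: int) -> np.ndarray:
        """Broadcast a 2D mask across ``n_planes`` z-planes (3D passthrough)."""
        return _as_3d(self.mask, n_planes)

    def cytosol_3d(self, n_planes: int) -> np.ndarray:
        if self.cytosol_sample is None:
            raise ValueError(f"cell {self.cell_id!r}: no cytosol sample defined")
        return _as_3d(self.cytosol_sample, n_planes)


def _as_3d(mask: np.ndarray, n_planes: int) -> np.ndarray:
    if mask.ndim == 3:
        return mask
    return np.broadcast_to(mask, (n_planes, *mask.shape))


@dataclass
class TimeLapse:
    """Ordered single-plane frames with a fixed frame interval.

    Invariants: at least two frames, all frames the same shape, and a
    strictly positive frame interval.
    """

    frames: np.ndarray           # (t, y, x)
    frame_interval: float        # seconds
    pixel_size: float            # μm / pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (t, y, x) array with >= 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class OrganelleSegment:
    """One labelled connected object from a 3D segmentation."""

    label: int
    voxel_indices: np.ndarray     # (n, 3) int array of (z, y, x)
    volume: float                 # μm³
    centroid: tuple[float, float, float]   # (x, y, z) μm
    cell_id: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


# ---------------------------------------------------------------------------
# pixel-center coordinate helpers
# ---------------------------------------------------------------------------

def centers_um(indices: np.ndarray, spacing: float) -> np.ndarray:
    """Physical center coordinates of integer pixel indices."""
    return (np.asarray(indices, dtype=float) + 0.5) * spacing


def index_grid_um(shape: tuple[int, ...], spacings: tuple[float, ...]):
    """Per-axis 1D arrays of pixel-center coordinates in μm.

    ``shape`` and ``spacings`` are given in array order (e.g. ``(z, y, x)``
    with spacings ``(sz, sy, sx)``).
    """
    return tuple(centers_um(np.arange(n), s) for n, s in zip(shape, spacings))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_stack_tiff(path: str | Path, channels: np.ndarray | list[np.ndarray]) -> None:
    """Write channels as an ImageJ-compatible multi-page TIFF (axes TZYX→CZYX).

    ``channels`` is a list of ``(z, y, x)`` arrays (or a single array); data
    are stored as float32 with an explicit ImageJ axes tag so standard
    viewers reconstruct the hyperstack.
    """
    data = np.asarray(channels, dtype=np.float32)
    if data.ndim == 3:
        data = data[None]
    # ImageJ hyperstack order is TZCYX; we store channels on the T axis so
    # each channel round-trips as one series.
    tifffile.imwrite(str(path), data, imagej=True, metadata={"axes": "TZYX"})


def read_stack_tiff(path: str | Path) -> np.ndarray:
    """Read a TIFF written by :func:`write_stack_tiff`; returns (c, z, y, x)."""
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    while data.ndim < 4:
        data = data[None]
    return data


def write_rois_json(path: str | Path, cells: list[CellRegion]) -> None:
    """Serialize cell regions as JSON (masks run-length encoded per row)."""
    payload = []
    for cell in cells:
        payload.append({
            "cell_id": cell.cell_id,
            "shape": list(cell.mask.shape),
            "mask_rle": _rle_encode(cell.mask),
            "cytosol_rle": (_rle_encode(cell.cytosol_sample)
                            if cell.cytosol_sample is not None else None),
        })
    Path(path).write_text(json.dumps(payload))


def read_rois_json(path: str | Path) -> list[CellRegion]:
    payload = json.loads(Path(path).read_text())
    cells = []
    for entry in payload:
        shape = tuple(entry["shape"])
        mask = _rle_decode(entry["mask_rle"], shape)
        cyt = (_rle_decode(entry["cytosol_rle"], shape)
               if entry.get("cytosol_rle") is not None else None)
        cells.append(CellRegion(entry["cell_id"], mask, cyt))
    return cells


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    # run lengths of alternating False/True runs, starting with False
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


def segments_to_frame(segments: list[OrganelleSegment]) -> pd.DataFrame:
    """Tidy per-segment table (label, cell_id, volume_um3, centroid_x/y/z)."""
    rows = [{
        "label": s.label,
        "cell_id": s.cell_id,
        "volume_um3": s.volume,
        "centroid_x": s.centroid[0],
        "centroid_y": s.centroid[1],
        "centroid_z": s.centroid[2],
        "n_voxels": s.n_voxels,
    } for s in segments]
    return pd.DataFrame(rows, columns=["label", "cell_id", "volume_um3",
                                       "centroid_x", "centroid_y", "centroid_z",
                                       "n_voxels"])
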