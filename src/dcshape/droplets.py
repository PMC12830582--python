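"""Label-free counting of dark intracellular lipid-droplet inclusions.

Lipid droplets appear in brightfield DC crops as compact dark spots in
the cytoplasm.  The detector is a six-step relative-threshold pipeline
run inside the segmented cell mask:

1. erode the mask to exclude the diffraction rim;
2. take the median m and intensity range r inside the eroded mask;
3. mark pixels darker than m - relative_threshold * r;
4. 8-connected component labelling;
5. gate components by area (min pixels, max fraction of the cell);
6. count survivors and record their areas.

The threshold is *relative* to the within-cell intensity range, so the
count is robust to illumination differences between runs.  Counts are
integers per cell; sample-level metrics (droplets per cell, droplet
area per cell) are averages over intact-labelled cells and therefore
non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .events import EventClass


@dataclass
class DropletParams:
    """Knobs of the inclusion detector."""

    relative_threshold: float = 0.35
    min_droplet_area_px: int = 4
    max_droplet_area_fraction: float = 0.25
    erosion_margin_px: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_threshold < 1.0:
            raise ValueError("relative_threshold must be in (0, 1)")
        if self.min_droplet_area_px < 1:
            raise ValueError("min_droplet_area_px must be >= 1")


@dataclass
class DropletResult:
    """Per-event droplet detection outcome."""

    event_id: int
    n_droplets: int
    droplet_areas_px2: list[float] = field(default_factory=list)
    total_droplet_area_fraction: float = 0.0
    empty_mask_flag: bool = False


def detect_droplets(crop: np.ndarray, mask: np.ndarray,
                    params: DropletParams | None = None,
                    event_id: int = -1) -> DropletResult:
    """Count dark inclusions inside one segmented cell."""
    params = params or DropletParams()
    crop = np.asarray(crop, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if crop.shape != mask.shape:
        raise ValueError("crop and mask shapes differ")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(f"mask must have exactly 1 component, got {n_comp}")

    eroded = mask
    if params.erosion_margin_px > 0:
        # Euclidean-distance erosion: strictly removes every pixel within
        # erosion_margin_px of the boundary (a discrete disk footprint
        # would leave corner pixels at exactly that distance in place)
        eroded = ndimage.distance_transform_edt(mask) > params.erosion_margin_px
    if not eroded.any():
        return DropletResult(event_id=event_id, n_droplets=0,
                             empty_mask_flag=True)

    inside = crop[eroded]
    m = np.median(inside)
    r = inside.max() - inside.min()
    if r <= 0:
        return DropletResult(event_id=event_id, n_droplets=0)
    candidates = eroded & (crop < m - params.relative_threshold * r)
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    cell_area = mask.sum()
    max_area = params.max_droplet_area_fraction * cell_area
    areas = []
    for lab in range(1, n + 1):
        a = int(np.sum(labels == lab))
        if params.min_droplet_area_px <= a <= max_area:
            areas.append(float(a))
    return DropletResult(
        event_id=event_id,
        n_droplets=len(areas),
        droplet_areas_px2=areas,
        total_droplet_area_fraction=float(sum(areas) / cell_area),
    )


def droplet_sample_stats(results: list[DropletResult],
                         class_labels: np.ndarray | list) -> dict:
    """Sample-level droplet metrics over intact-labelled events.

    Returns the mean droplet count per cell, the mean total droplet
    area per cell (px^2), and the number of cells used.
    """
    if len(results) != len(class_labels):
        raise ValueError("results and class_labels not aligned")
    labels = np.asarray(
        [l.value if isinstance(l, EventClass) else str(l) for l in class_labels])
    intact = labels == EventClass.INTACT.value
    if not intact.any():
        raise ValueError("no intact-labelled events to average over")
    counts = np.asarray([r.n_droplets for r in results], dtype=float)[intact]
    areas = np.asarray([sum(r.droplet_areas_px2) for r in results],
                       dtype=float)[intact]
    return {
        "mean_droplets_per_cell": float(counts.mean()),
        "mean_droplet_area_per_cell": float(areas.mean()),
        "n_cells": int(intact.sum()),
    }
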