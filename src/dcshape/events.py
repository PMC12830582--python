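"""Core event vocabulary shared across the pipeline.

Deformability cytometry (DC) streams brightfield frames of single objects
("events") passing a microfluidic constriction.  Every detected object is
assigned one of five image classes; the enumeration and its stable integer
encoding are defined here once and re-used by the generator, the segmenter
and the classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class EventClass(str, enum.Enum):
    """The five DC event-image classes.

    Integer encoding (see :data:`CLASS_INDEX`) is stable and recorded in
    every trained-model manifest.
    """

    INTACT = "intact"
    ANOMALOUS = "anomalous"
    DEAD = "dead"
    AGGREGATE = "aggregate"
    DEBRIS = "debris"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stable label -> integer encoding used in stores and model manifests.
CLASS_INDEX: dict[EventClass, int] = {c: i for i, c in enumerate(EventClass)}
#: Inverse mapping.
INDEX_CLASS: dict[int, EventClass] = {i: c for c, i in CLASS_INDEX.items()}
#: Class names in encoding order.
CLASS_NAMES: list[str] = [c.value for c in EventClass]

N_CLASSES = len(EventClass)


@dataclass
class EventRecord:
    """One segmented object.

    Attributes
    ----------
    event_id:
        Unique integer id within a run.
    frame_index:
        Index of the source frame.
    bbox:
        ``(row0, col0, row1, col1)`` half-open bounding box of the *crop*
        in frame coordinates (includes the margin).
    mask:
        Binary crop-sized mask with exactly one connected component,
        holes filled.
    contour:
        Closed polygon ``(n, 2)`` of (row, col) vertices in crop
        coordinates; first vertex repeated as last; counter-clockwise.
    crop:
        Raw 8-bit sub-image, same shape as ``mask``.
    """

    event_id: int
    frame_index: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    contour: np.ndarray
    crop: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.crop = np.asarray(self.crop)
        self.contour = np.asarray(self.contour, dtype=float)
        if self.mask.shape != self.crop.shape:
            raise ValueError(
                f"event {self.event_id}: mask shape {self.mask.shape} != "
                f"crop shape {self.crop.shape}"
            )

    @property
    def area_px(self) -> int:
        """Pixel count of the mask."""
        return int(self.mask.sum())


@dataclass
class SampleSummary:
    """Per-sample aggregate reported instead of manual gating.

    ``class_fractions`` are computed over *all* events and sum to 1;
    the deformation/area modes and the droplet average are restricted to
    intact-labelled events, the physiologically meaningful subpopulation.
    """

    class_fractions: dict[str, float]
    mode_deformation: float
    mode_area_um2: float
    mean_droplets_per_cell: float
    n_events: int
    n_intact: int
    low_count_warning: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_fractions": dict(self.class_fractions),
            "mode_deformation": self.mode_deformation,
            "mode_area_um2": self.mode_area_um2,
            "mean_droplets_per_cell": self.mean_droplets_per_cell,
            "n_events": self.n_events,
            "n_intact": self.n_intact,
            "low_count_warning": self.low_count_warning,
            **self.extras,
        }
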