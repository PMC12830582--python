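"""Frame input and the HDF5 event store.

Frames come in as 8-bit multi-page TIFF stacks or directories of 8-bit
images; anything else is rejected rather than silently rescaled, since
gray-level thresholds are calibrated for the instrument's 8-bit output.

Segmented events live in a single HDF5 container.  Crops, masks and
contours genuinely vary in size, so they are stored as ragged datasets
(flattened values plus per-event shapes/lengths) — padding to a common
shape would corrupt the morphometry.  The layout is deliberately close
in spirit to the community ``.rtdc`` HDF5 convention (events + aligned
feature columns + metadata), without claiming bit-compatibility:

    /events/event_id, /events/frame_index, /events/bbox
    /events/image_data + image_shape   (ragged uint8 crops)
    /events/mask_data  + mask_shape    (ragged boolean masks)
    /events/contour_data + contour_len (ragged float polygons)
    /features/<name>                   (aligned 1-D columns)
    /meta                              (JSON config snapshot)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventRecord

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}


@dataclass
class Frame:
    """One acquisition frame."""

    pixels: np.ndarray
    frame_index: int
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError(
                f"frame {self.frame_index}: dtype {self.pixels.dtype} is not "
                "8-bit unsigned; refusing to rescale silently")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def read_frames(path: str | Path, pixel_size_um: float | None = None):
    """Yield :class:`Frame` objects from a TIFF stack or image directory.

    Frames are yielded in index order (TIFF page order, or sorted file
    name order for a directory).  Mixed shapes or non-8-bit data raise.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image files in directory {path}")
        shape = None
        for i, f in enumerate(files):
            try:
                import imageio.v3 as iio

                arr = iio.imread(f)
            except Exception as exc:  # noqa: BLE001
                raise OSError(f"unreadable image file {f}: {exc}") from exc
            if arr.ndim == 3:
                arr = arr[..., 0]
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"mixed frame shapes: {f} has {arr.shape}, expected {shape}")
            yield Frame(pixels=arr, frame_index=i, pixel_size_um=pixel_size_um)
        return
    if not path.exists():
        raise FileNotFoundError(path)
    import tifffile

    with tifffile.TiffFile(path) as tf:
        shape = None
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if arr.ndim == 3:
                arr = arr[..., 0]
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"mixed frame shapes: page {i} has {arr.shape}, "
                    f"expected {shape}")
            yield Frame(pixels=arr, frame_index=i, pixel_size_um=pixel_size_um)


def write_frames_tiff(frames: np.ndarray, path: str | Path) -> None:
    """Write an (n, H, W) uint8 stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))


# ---------------------------------------------------------------------------
# event store


def _ragged_pack(arrays: list[np.ndarray], dtype):
    if not arrays:
        return np.zeros(0, dtype=dtype), np.zeros((0, 2), dtype=np.int64)
    flat = np.concatenate([np.asarray(a, dtype=dtype).ravel()
                           for a in arrays])
    shapes = np.asarray([a.shape for a in arrays], dtype=np.int64)
    return flat, shapes


def write_event_store(events: list[EventRecord], features: dict[str, np.ndarray],
                      meta: dict, path: str | Path) -> None:
    """Persist events + aligned feature columns + metadata.

    Round-trip is bit-exact.  Raises if any feature column length
    differs from the number of events.
    """
    n = len(events)
    for name, col in features.items():
        if len(col) != n:
            raise ValueError(
                f"feature '{name}' has length {len(col)}, but there are "
                f"{n} events")
    img_flat, img_shapes = _ragged_pack([e.crop for e in events], np.uint8)
    msk_flat, msk_shapes = _ragged_pack(
        [e.mask.astype(np.uint8) for e in events], np.uint8)
    cnt_flat, _ = _ragged_pack([e.contour for e in events], np.float64)
    cnt_len = np.asarray([len(e.contour) for e in events], dtype=np.int64)

    with h5py.File(path, "w") as h5:
        ev = h5.create_group("events")
        ev.create_dataset("event_id",
                          data=np.asarray([e.event_id for e in events],
                                          dtype=np.int64))
        ev.create_dataset("frame_index",
                          data=np.asarray([e.frame_index for e in events],
                                          dtype=np.int64))
        ev.create_dataset("bbox",
                          data=np.asarray([e.bbox for e in events],
                                          dtype=np.int64).reshape(n, 4))
        ev.create_dataset("image_data", data=img_flat)
        ev.create_dataset("image_shape", data=img_shapes)
        ev.create_dataset("mask_data", data=msk_flat)
        ev.create_dataset("mask_shape", data=msk_shapes)
        ev.create_dataset("contour_data", data=cnt_flat)
        ev.create_dataset("contour_len", data=cnt_len)
        ft = h5.create_group("features")
        for name, col in features.items():
            col = np.asarray(col)
            if col.dtype.kind in "US":
                col = col.astype(h5py.string_dtype())
            ft.create_dataset(name, data=col)
        h5.create_dataset("meta", data=json.dumps(meta, sort_keys=True))


@dataclass
class EventStoreData:
    """In-memory view of a read event store."""

    events: list[EventRecord]
    features: dict[str, np.ndarray]
    meta: dict
    missing_features: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.events)


_EXPECTED_FEATURES = ("area_px2", "area_um2", "perimeter_px", "deform",
                      "class_label", "class_prob", "n_droplets")


def read_event_store(path: str | Path) -> EventStoreData:
    """Read a store back; validates length consistency across datasets."""
    with h5py.File(path, "r") as h5:
        ev = h5["events"]
        eid = ev["event_id"][:]
        n = len(eid)
        fidx = ev["frame_index"][:]
        bbox = ev["bbox"][:].reshape(n, 4) if n else np.zeros((0, 4),
                                                             dtype=np.int64)
        img_shapes = ev["image_shape"][:].reshape(n, 2)
        msk_shapes = ev["mask_shape"][:].reshape(n, 2)
        cnt_len = ev["contour_len"][:]
        for name, ln in (("frame_index", len(fidx)), ("bbox", len(bbox)),
                         ("image_shape", len(img_shapes)),
                         ("mask_shape", len(msk_shapes)),
                         ("contour_len", len(cnt_len))):
            if ln != n:
                raise ValueError(
                    f"store inconsistent: /events/{name} has length {ln}, "
                    f"event_id has {n}")
        img_flat = ev["image_data"][:]
        msk_flat = ev["mask_data"][:]
        cnt_flat = ev["contour_data"][:]
        events = []
        io = mo = co = 0
        for i in range(n):
            ih, iw = img_shapes[i]
            mh, mw = msk_shapes[i]
            crop = img_flat[io:io + ih * iw].reshape(ih, iw)
            mask = msk_flat[mo:mo + mh * mw].reshape(mh, mw).astype(bool)
            k = int(cnt_len[i])
            contour = cnt_flat[co:co + 2 * k].reshape(k, 2)
            io += ih * iw
            mo += mh * mw
            co += 2 * k
            events.append(EventRecord(
                event_id=int(eid[i]), frame_index=int(fidx[i]),
                bbox=tuple(int(v) for v in bbox[i]), mask=mask,
                contour=contour, crop=crop))
        features = {}
        for name in h5["features"]:
            col = h5["features"][name][:]
            if col.dtype.kind == "O":
                col = np.asarray([v.decode() if isinstance(v, bytes) else v
                                  for v in col])
            if len(col) != n:
                raise ValueError(
                    f"store inconsistent: /features/{name} has length "
                    f"{len(col)}, events have {n}")
            features[name] = col
        meta = json.loads(h5["meta"][()])
    missing = tuple(f for f in _EXPECTED_FEATURES if f not in features)
    return EventStoreData(events=events, features=features, meta=meta,
                         missing_features=missing)


def export_features_csv(store: EventStoreData, path: str | Path) -> pd.DataFrame:
    """Flat per-event feature table (one row per event)."""
    n = len(store)
    cols: dict[str, np.ndarray] = {
        "event_id": np.asarray([e.event_id for e in store.events]),
        "frame_index": np.asarray([e.frame_index for e in store.events]),
    }
    for name in _EXPECTED_FEATURES:
        if name in store.features:
            cols[name] = store.features[name]
        else:
            cols[name] = np.full(n, np.nan)
    for name, col in store.features.items():
        if name not in cols:
            cols[name] = col
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.10g")
    return df
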