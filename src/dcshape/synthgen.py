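"""Synthetic deformability-cytometry frame and crop generator.

Emulates a brightfield DC acquisition (8-bit frames from a microfluidic
channel imaged with sub-microsecond strobed flashes) with exact ground
truth: every rendered object carries its class, an analytic boundary
polygon, and the centres/radii of any planted lipid droplets.  The five
event classes mirror what a DC instrument sees in a lymphocyte sample:

``intact``
    smooth ellipse, bright diffraction rim, darker interior;
``anomalous``
    ellipse with a radial-sinusoid boundary perturbation and blotchy
    internal texture — deliberately the hardest boundary against intact;
``dead``
    small, low-contrast, high-granularity object;
``aggregate``
    union of 2–4 overlapping ellipses (may be *smaller* in total area
    than a large intact cell, so size alone cannot gate it out);
``debris``
    irregular blob well below a quarter of the median intact area.

Renderings are parameterised caricatures, not photorealism: every
contrast, texture and perturbation amplitude is a knob, and a ``hard``
mode narrows the intact-vs-anomalous perturbation gap.

Coordinates are (row, col), 0-based, origin top-left; boundary polygons
are closed (first vertex repeated last) in pixel-centre coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union
from skimage.draw import polygon2mask

from .events import EventClass

_BOUNDARY_VERTICES = 720
_PATCH_MARGIN = 6
_RIM_WIDTH = 2.0
_DEFAULT_CROP_BACKGROUND = 180.0

#: Sizes of the manually curated Jurkat training set this generator
#: emulates (intact, anomalous, dead, aggregate, debris).
REFERENCE_TRAINING_COUNTS: dict[EventClass, int] = {
    EventClass.INTACT: 4904,
    EventClass.ANOMALOUS: 1456,
    EventClass.DEAD: 2525,
    EventClass.AGGREGATE: 784,
    EventClass.DEBRIS: 1829,
}


@dataclass
class ObjectSpec:
    """Parameters of one synthetic object.

    ``intensity_offset`` is the interior gray-level offset relative to
    the local background (negative = darker, the brightfield
    convention); ``texture_sigma`` the internal texture amplitude in
    gray levels.  ``boundary_amp``/``boundary_lobes``/``boundary_phase``
    describe the radial-sinusoid boundary perturbation r(θ) = r₀·(1 +
    amp·sin(lobes·θ + phase)) used by anomalous cells and debris.
    ``sub_ellipses`` (aggregates only) lists member ellipses as
    ``(d_row, d_col, a, b, orientation)`` relative to ``center``.
    """

    object_class: EventClass
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0
    intensity_offset: float = -35.0
    texture_sigma: float = 4.0
    texture_smooth: float = 2.0
    n_droplets: int = 0
    droplet_radius_px: float = 3.0
    droplet_contrast: float = 60.0
    boundary_amp: float = 0.0
    boundary_lobes: int = 0
    boundary_phase: float = 0.0
    sub_ellipses: tuple = ()
    rim_gain: float = 28.0
    object_id: int = -1

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        if self.object_class is EventClass.AGGREGATE and not self.sub_ellipses:
            raise ValueError("aggregate spec requires sub_ellipses")


@dataclass
class FrameSpec:
    """Parameters of one synthetic frame."""

    height: int = 96
    width: int = 256
    background_level: float = 180.0
    background_gradient: float = 10.0
    noise_sigma: float = 2.0
    objects: list[ObjectSpec] = field(default_factory=list)
    channel_wall_rows: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo = self.background_level - abs(self.background_gradient) / 2
        hi = self.background_level + abs(self.background_gradient) / 2
        if lo < 0 or hi > 255:
            raise ValueError("background level/gradient exceed the 8-bit range")


@dataclass
class GroundTruthObject:
    object_id: int
    frame_index: int
    object_class: EventClass
    polygon: np.ndarray  # closed (n, 2) row/col in frame coordinates
    area: float
    perimeter: float
    n_droplets: int
    droplet_centers: np.ndarray  # (k, 2) row/col in frame coordinates
    droplet_radii: np.ndarray


@dataclass
class GroundTruthManifest:
    """Per-object ground truth for a rendered frame sequence."""

    objects: list[GroundTruthObject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objects)

    def for_frame(self, frame_index: int) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.frame_index == frame_index]

    def to_files(self, csv_path: str | Path, json_path: str | Path) -> None:
        """CSV of scalar fields plus a JSON sidecar holding the polygons."""
        rows, sidecar = [], {}
        for o in self.objects:
            rows.append(
                {
                    "object_id": o.object_id,
                    "frame_index": o.frame_index,
                    "object_class": o.object_class.value,
                    "area": o.area,
                    "perimeter": o.perimeter,
                    "n_droplets": o.n_droplets,
                }
            )
            sidecar[str(o.object_id)] = {
                "polygon": np.asarray(o.polygon).tolist(),
                "droplet_centers": np.asarray(o.droplet_centers).tolist(),
                "droplet_radii": np.asarray(o.droplet_radii).tolist(),
            }
        pd.DataFrame(rows, columns=["object_id", "frame_index", "object_class",
                                    "area", "perimeter", "n_droplets"]).to_csv(
            csv_path, index=False)
        Path(json_path).write_text(json.dumps(sidecar))

    @classmethod
    def from_files(cls, csv_path: str | Path, json_path: str | Path
                   ) -> "GroundTruthManifest":
        df = pd.read_csv(csv_path)
        sidecar = json.loads(Path(json_path).read_text())
        objs = []
        for _, r in df.iterrows():
            extra = sidecar[str(int(r.object_id))]
            objs.append(GroundTruthObject(
                object_id=int(r.object_id),
                frame_index=int(r.frame_index),
                object_class=EventClass(r.object_class),
                polygon=np.asarray(extra["polygon"], dtype=float),
                area=float(r.area),
                perimeter=float(r.perimeter),
                n_droplets=int(r.n_droplets),
                droplet_centers=np.asarray(extra["droplet_centers"],
                                           dtype=float).reshape(-1, 2),
                droplet_radii=np.asarray(extra["droplet_radii"], dtype=float),
            ))
        return cls(objs)


# ---------------------------------------------------------------------------
# geometry


def _perturbed_ellipse(center, semi_axes, orientation, amp, lobes, phase,
                       n=_BOUNDARY_VERTICES) -> np.ndarray:
    """Closed (n+1, 2) row/col polygon of a radially perturbed ellipse."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    a, b = semi_axes
    scale = 1.0 + (amp * np.sin(lobes * theta + phase) if amp else 0.0)
    x = a * np.cos(theta) * scale
    y = b * np.sin(theta) * scale
    ct, st = np.cos(orientation), np.sin(orientation)
    col = center[1] + ct * x - st * y
    row = center[0] + st * x + ct * y
    poly = np.column_stack([row, col])
    return np.vstack([poly, poly[:1]])


def _shapely_of(poly: np.ndarray) -> ShapelyPolygon:
    # shapely works in (x, y); map col -> x, row -> y
    return ShapelyPolygon(np.column_stack([poly[:, 1], poly[:, 0]]))


def _from_shapely(sp: ShapelyPolygon) -> np.ndarray:
    x, y = sp.exterior.coords.xy
    return np.column_stack([np.asarray(y), np.asarray(x)])


def boundary_polygon(spec: ObjectSpec) -> np.ndarray:
    """Analytic closed boundary polygon of an object, frame coordinates."""
    if spec.object_class is EventClass.AGGREGATE:
        members = []
        for d_row, d_col, a, b, th in spec.sub_ellipses:
            c = (spec.center[0] + d_row, spec.center[1] + d_col)
            members.append(_shapely_of(
                _perturbed_ellipse(c, (a, b), th, 0.0, 0, 0.0)))
        union = unary_union(members)
        if union.geom_type != "Polygon":
            raise ValueError(
                f"object {spec.object_id}: aggregate members do not overlap "
                "into a single connected component")
        return _from_shapely(union)
    return _perturbed_ellipse(spec.center, spec.semi_axes, spec.orientation,
                              spec.boundary_amp, spec.boundary_lobes,
                              spec.boundary_phase)


def polygon_bounds(poly: np.ndarray) -> tuple[float, float, float, float]:
    return (poly[:, 0].min(), poly[:, 1].min(),
            poly[:, 0].max(), poly[:, 1].max())


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderedObject:
    """Internal full rendering result (offset field + ground truth)."""

    field: np.ndarray        # float gray-level offsets, patch coordinates
    mask: np.ndarray         # bool, patch coordinates
    origin: tuple[int, int]  # (row0, col0) of the patch in the frame
    polygon: np.ndarray      # closed, frame coordinates
    droplet_centers: np.ndarray  # frame coordinates
    droplet_radii: np.ndarray
    area: float
    perimeter: float


def _place_droplets(spec: ObjectSpec, mask: np.ndarray, rng: np.random.Generator,
                    max_tries: int = 600) -> np.ndarray:
    """Sample disjoint droplet centres inside the eroded mask (patch coords)."""
    if spec.n_droplets == 0:
        return np.zeros((0, 2))
    r = spec.droplet_radius_px
    # keep droplets clear of the rim so rim shading never clips them
    allowed = distance_transform_edt(mask) > (r + _RIM_WIDTH + 1.5)
    rows, cols = np.nonzero(allowed)
    if rows.size == 0:
        raise ValueError(
            f"object {spec.object_id}: no room for droplets of radius {r}")
    # rejection sampling with restarts: a crowded partial layout can leave
    # no room for the remaining droplets, so re-deal rather than grind
    for _restart in range(30):
        centers: list[tuple[float, float]] = []
        for _ in range(max_tries):
            i = rng.integers(rows.size)
            cand = (float(rows[i]), float(cols[i]))
            if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2 * r + 1.5
                   for c in centers):
                centers.append(cand)
                if len(centers) == spec.n_droplets:
                    return np.asarray(centers)
    raise ValueError(
        f"object {spec.object_id}: could not place {spec.n_droplets} "
        f"disjoint droplets after {30 * max_tries} tries")


def render_object_full(spec: ObjectSpec, rng: np.random.Generator
                       ) -> RenderedObject:
    poly = boundary_polygon(spec)
    r0, c0, r1, c1 = polygon_bounds(poly)
    row0 = int(np.floor(r0)) - _PATCH_MARGIN
    col0 = int(np.floor(c0)) - _PATCH_MARGIN
    h = int(np.ceil(r1)) - row0 + 1 + _PATCH_MARGIN
    w = int(np.ceil(c1)) - col0 + 1 + _PATCH_MARGIN
    local = poly - np.array([row0, col0])
    mask = polygon2mask((h, w), local)
    if not mask.any():
        raise ValueError(f"object {spec.object_id}: degenerate mask")

    dist_in = distance_transform_edt(mask)
    fld = np.zeros((h, w), dtype=float)
    interior = dist_in > _RIM_WIDTH
    fld[interior] = spec.intensity_offset
    rim = (dist_in > 0) & ~interior
    fld[rim] = spec.rim_gain

    if spec.texture_sigma > 0:
        tex = rng.normal(size=(h, w))
        if spec.texture_smooth > 0:
            tex = gaussian_filter(tex, spec.texture_smooth)
            tex /= max(tex.std(), 1e-9)
        fld[interior] += spec.texture_sigma * tex[interior]

    centers = _place_droplets(spec, mask, rng)
    for (dr, dc) in centers:
        rr = np.arange(h)[:, None] - dr
        cc = np.arange(w)[None, :] - dc
        d = np.hypot(rr, cc)
        fld -= spec.droplet_contrast * np.clip(spec.droplet_radius_px + 0.5 - d,
                                               0.0, 1.0)
    fld = gaussian_filter(fld, 0.6)  # soft optical edges

    sp = _shapely_of(poly)
    return RenderedObject(
        field=fld, mask=mask, origin=(row0, col0), polygon=poly,
        droplet_centers=centers + np.array([row0, col0]),
        droplet_radii=np.full(len(centers), spec.droplet_radius_px),
        area=sp.area, perimeter=sp.length,
    )


def render_object(spec: ObjectSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render one object on a flat default background.

    Returns the 8-bit patch and the boolean mask (same shape).
    """
    ro = render_object_full(spec, rng)
    patch = _DEFAULT_CROP_BACKGROUND + ro.field
    patch += rng.normal(0.0, 2.0, size=patch.shape)
    return np.clip(np.round(patch), 0, 255).astype(np.uint8), ro.mask


# ---------------------------------------------------------------------------
# object sampling (the default study conditions)


def sample_object_spec(object_class: EventClass, rng: np.random.Generator,
                       center: tuple[float, float] = (0.0, 0.0),
                       n_droplets: int = 0, hard: bool = False) -> ObjectSpec:
    """Draw a class-typical ObjectSpec at the given centre.

    ``hard`` narrows the intact-vs-anomalous boundary-perturbation gap,
    the knob that controls classifier difficulty.
    """
    u = rng.uniform
    if object_class is EventClass.INTACT:
        a = u(18.0, 28.0)
        b = a * u(0.78, 0.98)
        return ObjectSpec(object_class, center, (a, b), u(0, np.pi),
                          intensity_offset=u(-40, -28), texture_sigma=u(3, 6),
                          texture_smooth=2.0, n_droplets=n_droplets)
    if object_class is EventClass.ANOMALOUS:
        a = u(16.0, 30.0)
        b = a * u(0.7, 0.95)
        amp = u(0.06, 0.12) if hard else u(0.15, 0.30)
        return ObjectSpec(object_class, center, (a, b), u(0, np.pi),
                          intensity_offset=u(-40, -25),
                          texture_sigma=u(10, 16), texture_smooth=3.0,
                          n_droplets=n_droplets,
                          boundary_amp=amp, boundary_lobes=int(rng.integers(5, 9)),
                          boundary_phase=u(0, 2 * np.pi))
    if object_class is EventClass.DEAD:
        a = u(7.0, 11.0)
        b = a * u(0.75, 1.0)
        return ObjectSpec(object_class, center, (a, b), u(0, np.pi),
                          intensity_offset=u(-18, -10),
                          texture_sigma=u(10, 16), texture_smooth=0.0,
                          rim_gain=u(5, 12))
    if object_class is EventClass.AGGREGATE:
        k = int(rng.integers(2, 5))
        members = []
        prev = (0.0, 0.0)
        for i in range(k):
            a = u(9.0, 16.0)
            b = a * u(0.8, 1.0)
            if i == 0:
                d = (0.0, 0.0)
            else:
                ang = u(0, 2 * np.pi)
                dist = u(0.45, 0.75) * (a + members[i - 1][2])
                d = (prev[0] + dist * np.sin(ang), prev[1] + dist * np.cos(ang))
            members.append((d[0], d[1], a, b, u(0, np.pi)))
            prev = d
        ext = max(abs(m[0]) + m[2] for m in members)
        return ObjectSpec(object_class, center, (ext, ext), 0.0,
                          intensity_offset=u(-40, -28), texture_sigma=u(4, 8),
                          texture_smooth=2.0, sub_ellipses=tuple(members))
    if object_class is EventClass.DEBRIS:
        a = u(3.5, 7.0)
        b = a * u(0.6, 1.0)
        return ObjectSpec(object_class, center, (a, b), u(0, np.pi),
                          intensity_offset=u(-35, -20),
                          texture_sigma=u(4, 8), texture_smooth=1.0,
                          rim_gain=u(0, 8),
                          boundary_amp=u(0.25, 0.45),
                          boundary_lobes=int(rng.integers(3, 7)),
                          boundary_phase=u(0, 2 * np.pi))
    raise ValueError(f"unknown class {object_class}")


def _object_radius(spec: ObjectSpec) -> float:
    poly = boundary_polygon(spec)
    r0, c0, r1, c1 = polygon_bounds(poly)
    return 0.5 * max(r1 - r0, c1 - c0)


def random_frame_specs(n_frames: int, objects_per_frame: int,
                       class_probs: dict[EventClass, float] | None = None,
                       seed: int = 0, droplet_range: tuple[int, int] = (0, 0),
                       hard: bool = False, max_tries: int = 400,
                       min_separation: float = 8.0, border_margin: float = 6.0,
                       **frame_kwargs) -> list[FrameSpec]:
    """Sample frame specs with non-touching object placement.

    Objects are rejection-sampled until their boundary polygons are at
    least ``min_separation`` px apart (comfortably above the 4 px
    no-touch guarantee, so that segmentation's morphological closing
    cannot bridge neighbours) and at least ``border_margin`` px inside
    the frame; saturation raises an error naming the frame.
    """
    rng = np.random.default_rng(seed)
    if class_probs is None:
        class_probs = {EventClass.INTACT: 1.0}
    classes = list(class_probs)
    probs = np.asarray([class_probs[c] for c in classes], dtype=float)
    probs /= probs.sum()
    base = FrameSpec(**frame_kwargs)
    specs = []
    next_id = 0
    for fi in range(n_frames):
        placed: list[ObjectSpec] = []
        placed_polys = []
        for _ in range(objects_per_frame):
            cls = classes[rng.choice(len(classes), p=probs)]
            nd = int(rng.integers(droplet_range[0], droplet_range[1] + 1)) \
                if droplet_range[1] > 0 and cls is EventClass.INTACT else 0
            ok = False
            for _try in range(max_tries):
                proto = sample_object_spec(cls, rng, hard=hard, n_droplets=nd)
                rad = _object_radius(proto) + border_margin
                if 2 * rad >= min(base.height, base.width):
                    continue
                row = rng.uniform(rad, base.height - rad)
                col = rng.uniform(rad, base.width - rad)
                cand = replace(proto, center=(row, col), object_id=next_id)
                poly = boundary_polygon(cand)
                r0, c0, r1, c1 = polygon_bounds(poly)
                if (r0 < border_margin or c0 < border_margin
                        or r1 > base.height - border_margin
                        or c1 > base.width - border_margin):
                    continue
                sp = _shapely_of(poly)
                if all(sp.distance(p) >= min_separation for p in placed_polys):
                    placed.append(cand)
                    placed_polys.append(sp)
                    next_id += 1
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"frame {fi}: cannot place object {len(placed) + 1} of "
                    f"{objects_per_frame} without touching (placement saturated)")
        specs.append(replace(base, objects=placed))
    return specs


# ---------------------------------------------------------------------------
# frame generation


def _background(spec: FrameSpec) -> np.ndarray:
    ramp = np.linspace(-0.5, 0.5, spec.width) * spec.background_gradient
    bg = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    bg += ramp[None, :]
    if spec.channel_wall_rows is not None:
        for r in spec.channel_wall_rows:
            bg[max(0, r - 1): r + 2, :] -= 70.0
    return bg


def generate_frames(specs: list[FrameSpec], seed: int
                    ) -> tuple[np.ndarray, GroundTruthManifest]:
    """Render frames from specs; deterministic in (specs, seed).

    Returns an (n_frames, H, W) uint8 stack and the manifest covering
    every rendered object.
    """
    rng = np.random.default_rng(seed)
    if not specs:
        return np.zeros((0, 0, 0), dtype=np.uint8), GroundTruthManifest()
    h, w = specs[0].height, specs[0].width
    frames = np.empty((len(specs), h, w), dtype=np.uint8)
    manifest = GroundTruthManifest()
    fallback_id = 0
    for fi, fs in enumerate(specs):
        if (fs.height, fs.width) != (h, w):
            raise ValueError(f"frame {fi}: inconsistent frame shape")
        img = _background(fs)
        polys = []
        for spec in fs.objects:
            ro = render_object_full(spec, rng)
            sp = _shapely_of(ro.polygon)
            for other in polys:
                if sp.distance(other) < 4.0:
                    raise ValueError(
                        f"frame {fi}: objects closer than 4 px; mark them "
                        "as one aggregate or respace the specs")
            polys.append(sp)
            pr0, pc0, pr1, pc1 = polygon_bounds(ro.polygon)
            if pr0 < 0 or pc0 < 0 or pr1 > h - 1 or pc1 > w - 1:
                raise ValueError(
                    f"frame {fi}: object {spec.object_id} exceeds frame bounds")
            # patch margin may poke past the frame edge; clip the paste
            r0, c0 = ro.origin
            ph, pw = ro.field.shape
            fr0, fc0 = max(0, r0), max(0, c0)
            fr1, fc1 = min(h, r0 + ph), min(w, c0 + pw)
            img[fr0:fr1, fc0:fc1] += ro.field[fr0 - r0:fr1 - r0,
                                              fc0 - c0:fc1 - c0]
            oid = spec.object_id if spec.object_id >= 0 else fallback_id
            fallback_id = max(fallback_id, oid + 1)
            manifest.objects.append(GroundTruthObject(
                object_id=oid, frame_index=fi,
                object_class=spec.object_class, polygon=ro.polygon,
                area=ro.area, perimeter=ro.perimeter,
                n_droplets=spec.n_droplets,
                droplet_centers=ro.droplet_centers,
                droplet_radii=ro.droplet_radii))
        if fs.noise_sigma > 0:
            img += rng.normal(0.0, fs.noise_sigma, size=img.shape)
        frames[fi] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return frames, manifest


# ---------------------------------------------------------------------------
# labelled training crops


def generate_labeled_arrays(counts: dict[EventClass, int], seed: int,
                            hard: bool = False,
                            droplet_range: tuple[int, int] = (0, 0),
                            ) -> tuple[list[np.ndarray], np.ndarray]:
    """In-memory labelled crops: (images, integer labels).

    Crop sizes vary with the sampled object geometry, as they do for a
    real instrument — downstream classifiers must accept ragged input.
    """
    from .events import CLASS_INDEX

    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for cls in EventClass:
        for _ in range(int(counts.get(cls, 0))):
            nd = 0
            if droplet_range[1] > 0 and cls is EventClass.INTACT:
                nd = int(rng.integers(droplet_range[0], droplet_range[1] + 1))
            spec = sample_object_spec(cls, rng, hard=hard, n_droplets=nd)
            patch, _ = render_object(spec, rng)
            images.append(patch)
            labels.append(CLASS_INDEX[cls])
    return images, np.asarray(labels, dtype=np.int64)


def generate_labeled_training_set(counts: dict[EventClass, int],
                                  out_dir: str | Path, seed: int,
                                  hard: bool = False) -> dict[str, int]:
    """Write per-class directories of PNG crops; returns written counts."""
    import imageio.v3 as iio

    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    written: dict[str, int] = {}
    for cls in EventClass:
        n = int(counts.get(cls, 0))
        if n < 0:
            raise ValueError(f"negative count for class {cls.value}")
        if n == 0:
            continue
        cdir = out / cls.value
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            spec = sample_object_spec(cls, rng, hard=hard)
            patch, _ = render_object(spec, rng)
            iio.imwrite(cdir / f"{cls.value}_{i:05d}.png", patch)
        written[cls.value] = n
    return written
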