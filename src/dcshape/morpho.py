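"""Contour morphometry: projected area, perimeter, and deformation.

The central statistic is the isoperimetric deformation

    D = 1 - 2*sqrt(pi*A) / l

with A the projected area and l the contour perimeter.  D is 0 for a
circle (isoperimetric identity), grows with elongation or boundary
irregularity, and is dimensionless and scale-invariant.  Because
digitisation noise can push D marginally below zero, D is clamped to
[0, 1); clamping events are counted, never hidden.

Per-sample summaries follow cytometry practice: class fractions over
all events, and the *mode* (argmax of a Gaussian KDE) of deformation
and area over intact-labelled cells, the robust location statistic for
skewed single-cell distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .events import CLASS_NAMES, EventClass, EventRecord, SampleSummary

#: Default camera calibration (micrometres per pixel).  A configuration
#: value, never derived from hardware names.
DEFAULT_PIXEL_SIZE_UM = 0.147

#: Per-experiment floor below which mode statistics are flagged.
MIN_CELLS_PER_EXPERIMENT = 900


@dataclass
class ContourFeatures:
    """Morphometric feature vector of one event."""

    A_px2: float
    A_um2: float
    l_px: float
    D: float
    centroid: tuple[float, float]
    aspect_ratio: float
    mean_brightness: float
    clamped: bool = False


@dataclass
class ModeEstimate:
    """KDE mode of a 1-D sample."""

    mode: float
    n: int
    bandwidth: float


def _close(contour: np.ndarray) -> np.ndarray:
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array")
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed polygon; orientation-independent."""
    c = _close(contour)
    if len(np.unique(c[:-1], axis=0)) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    y, x = c[:-1, 0], c[:-1, 1]
    y2, x2 = c[1:, 0], c[1:, 1]
    return float(abs(np.sum(x * y2 - x2 * y)) / 2.0)


def polygon_perimeter(contour: np.ndarray) -> float:
    """Sum of Euclidean edge lengths of a closed polygon."""
    c = _close(contour)
    if len(np.unique(c[:-1], axis=0)) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    return float(np.sum(np.hypot(*(np.diff(c, axis=0).T))))


def deformation(A_px2: float, l_px: float, clamp: bool = True
                ) -> tuple[float, bool]:
    """Isoperimetric deformation D = 1 - 2*sqrt(pi*A)/l.

    Returns ``(D, clamped)``; with ``clamp`` the value is forced into
    [0, 1) and ``clamped`` records whether that happened.
    """
    if A_px2 <= 0 or l_px <= 0:
        raise ValueError("area and perimeter must be positive")
    d = 1.0 - 2.0 * np.sqrt(np.pi * A_px2) / l_px
    if not clamp:
        return float(d), False
    clamped = d < 0.0 or d >= 1.0
    return float(np.clip(d, 0.0, np.nextafter(1.0, 0.0))), clamped


def _aspect_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio from central second moments (>= 1)."""
    rows, cols = np.nonzero(mask)
    r = rows - rows.mean()
    c = cols - cols.mean()
    # +1/12 per axis: variance of the uniform pixel footprint
    mrr = np.mean(r * r) + 1.0 / 12.0
    mcc = np.mean(c * c) + 1.0 / 12.0
    mrc = np.mean(r * c)
    common = np.sqrt((mrr - mcc) ** 2 + 4 * mrc ** 2)
    lam1 = (mrr + mcc + common) / 2.0
    lam2 = (mrr + mcc - common) / 2.0
    return float(np.sqrt(lam1 / max(lam2, 1e-12)))


def compute_event_features(event: EventRecord,
                           pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
                           ) -> ContourFeatures:
    """Assemble the full morphometric vector for one segmented event."""
    a = polygon_area(event.contour)
    l = polygon_perimeter(event.contour)
    d, clamped = deformation(a, l)
    rows, cols = np.nonzero(event.mask)
    centroid = (float(rows.mean()), float(cols.mean()))
    return ContourFeatures(
        A_px2=a,
        A_um2=a * pixel_size_um ** 2,
        l_px=l,
        D=d,
        centroid=centroid,
        aspect_ratio=_aspect_ratio(event.mask),
        mean_brightness=float(np.asarray(event.crop, dtype=float)[event.mask].mean()),
        clamped=clamped,
    )


def estimate_mode(values: np.ndarray, bandwidth_rule: str = "silverman",
                  grid_points: int = 512) -> ModeEstimate:
    """Mode of a 1-D sample as the argmax of a Gaussian KDE.

    Silverman's rule bandwidth by default; the KDE is evaluated on a
    regular grid spanning the sample range, so the result is
    deterministic and binning-free.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot estimate the mode of an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return ModeEstimate(mode=float(lo), n=v.size, bandwidth=0.0)
    kde = gaussian_kde(v, bw_method=bandwidth_rule)
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    return ModeEstimate(mode=float(grid[int(np.argmax(dens))]), n=v.size,
                        bandwidth=float(kde.factor * v.std(ddof=1)))


def summarize_sample(features: list[ContourFeatures],
                     class_labels: np.ndarray,
                     droplet_counts: np.ndarray | None = None,
                     min_intact: int = MIN_CELLS_PER_EXPERIMENT
                     ) -> SampleSummary:
    """Per-sample aggregate: class fractions, intact-cell modes, droplets.

    ``class_labels`` may be EventClass values, their names, or integer
    codes.  Fractions cover all events and sum to 1; mode(D),
    mode(area) and the droplet average use intact-labelled events only.
    A warning flag is raised when fewer intact cells than the
    per-experiment floor are available.
    """
    n = len(features)
    if n == 0:
        raise ValueError("cannot summarise an empty sample")
    labels = _normalize_labels(class_labels, n)
    fractions = {name: float(np.mean(labels == name)) for name in CLASS_NAMES}

    intact = labels == EventClass.INTACT.value
    n_intact = int(intact.sum())
    warn = n_intact < min_intact
    if warn:
        warnings.warn(
            f"only {n_intact} intact cells (< {min_intact}); mode "
            "statistics may be unstable", stacklevel=2)
    if n_intact > 0:
        d_vals = np.asarray([f.D for f in features])[intact]
        a_vals = np.asarray([f.A_um2 for f in features])[intact]
        mode_d = estimate_mode(d_vals).mode
        mode_a = estimate_mode(a_vals).mode
    else:
        mode_d = mode_a = float("nan")
    if droplet_counts is not None and n_intact > 0:
        mean_dr = float(np.asarray(droplet_counts, dtype=float)[intact].mean())
    else:
        mean_dr = float("nan") if droplet_counts is None else 0.0
    return SampleSummary(
        class_fractions=fractions,
        mode_deformation=mode_d,
        mode_area_um2=mode_a,
        mean_droplets_per_cell=mean_dr,
        n_events=n,
        n_intact=n_intact,
        low_count_warning=warn,
    )


def _normalize_labels(class_labels, n: int) -> np.ndarray:
    labels = np.asarray(class_labels)
    if labels.shape[0] != n:
        raise ValueError("class_labels not aligned with features")
    if labels.dtype.kind in "iu":
        from .events import INDEX_CLASS

        return np.asarray([INDEX_CLASS[int(i)].value for i in labels])
    return np.asarray([EventClass(str(l)).value for l in labels])
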