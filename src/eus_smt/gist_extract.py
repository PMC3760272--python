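"""GIST (gastrointestinal stromal tumor) extraction from endosonograms.

The extraction chain works on the characteristic appearance of a stromal
tumor on EUS: an intermediate-echogenicity, speckle-textured lesion
surrounded by bright boundary echoes, sitting in a dark acoustic background
together with the transducer disc and frame artifacts.  The stages, in
order:

1.  *Boundary-line suppression* — pixels darker than ``bright_floor``
    (default 30) are ineligible; boundary lines of extreme brightness can
    additionally be cut with an optional ``bright_ceiling``.
2.  *Edge linking* — an eligible pixel is linked to an adjacent eligible
    pixel when their Sobel gradient magnitudes differ by at most
    ``link_threshold`` (default 130); linked pixels form the candidate set.
3.  *Dark-pixel lift* — brightness values at or below ``dark_cutoff``
    (default 40) are raised to 255, which folds the dark interior of a
    hypoechoic lesion into the candidate region.
4.  Morphological closing, Butterworth low-pass smoothing, Canny boundary
    extraction, dilation + opening.
5.  GrassFire connected-component labeling and density-based object
    selection, discarding small, border-touching (lens/frame) and
    low-density (curvilinear) objects.

All stages are deterministic; the same image and configuration always
produce the same mask.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage
from skimage import feature, morphology

from .image_io import as_gray_image

__all__ = [
    "ExtractionConfig",
    "ObjectStats",
    "suppress_boundary_lines",
    "eligibility_mask",
    "gradient_magnitude",
    "edge_link",
    "suppress_dark",
    "morph_close",
    "butterworth_smooth",
    "canny_boundaries",
    "dilate_then_open",
    "grassfire_label",
    "object_stats",
    "select_tumor_object",
    "extract_object_from_mask",
    "extract_gist",
]


@dataclass
class ExtractionConfig:
    """Tunable parameters of the extraction chain.

    The brightness thresholds (30 / 130 / 40) are the experimentally
    determined values for standardized EUS frames; the morphology, filter
    and selection parameters are exposed because the source procedure does
    not pin them down numerically.
    """

    bright_floor: int = 30          # eligibility floor for edge linking
    link_threshold: float = 130.0   # max gradient-magnitude difference Th
    dark_cutoff: int = 40           # brightness <= cutoff is lifted to 255
    bright_ceiling: int | None = None  # optional high-side boundary cut (disabled)
    close_radius: int = 2
    dilate_radius: int = 2
    open_radius: int = 2
    butterworth_order: int = 2
    butterworth_cutoff: float = 0.3  # fraction of Nyquist, in (0, 1)
    canny_sigma: float = 1.4
    canny_low: float = 0.1           # normalized hysteresis thresholds
    canny_high: float = 0.3
    min_area: int = 200              # px, smallest plausible lesion
    min_density: float = 0.4         # area / bounding-box area
    lens_margin: int = 5             # border band excluding lens/frame objects
    connectivity: int = 8            # 4 or 8, for linking and labeling

    def __post_init__(self) -> None:
        if not 0 <= self.bright_floor <= 255:
            raise ValueError("bright_floor must be in [0, 255]")
        if not 0 <= self.dark_cutoff <= 255:
            raise ValueError("dark_cutoff must be in [0, 255]")
        if self.link_threshold < 0:
            raise ValueError("link_threshold must be >= 0")
        for name in ("close_radius", "dilate_radius", "open_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.min_density <= 1:
            raise ValueError("min_density must be in (0, 1]")
        if not 0 < self.butterworth_cutoff < 1:
            raise ValueError("butterworth_cutoff must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown extraction config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# pixel-level stages


def eligibility_mask(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Pixels bright enough (and, optionally, dim enough) to take part in
    edge linking."""
    img = as_gray_image(img)
    elig = img >= cfg.bright_floor
    if cfg.bright_ceiling is not None:
        elig &= img <= cfg.bright_ceiling
    return elig


def suppress_boundary_lines(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Zero out pixels of extreme brightness (boundary lines, background).

    Returns a copy of the image with ineligible pixels set to 0; the
    surviving nonzero pixels are exactly ``eligibility_mask(img, cfg)``
    (up to eligible pixels that were already 0, which only occur when
    ``bright_floor`` is 0).
    """
    out = as_gray_image(img)
    out[~eligibility_mask(img, cfg)] = 0
    return out


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel 3x3 gradient magnitude as float64."""
    f = np.asarray(img, dtype=np.float64)
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    return np.hypot(gy, gx)


_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _shifted(a: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    """Array shifted so that out[y, x] = a[y + dy, x + dx], padded with fill."""
    out = np.full_like(a, fill)
    h, w = a.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys_src = slice(max(0, dy), min(h, h + dy))
    xs_src = slice(max(0, dx), min(w, w + dx))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def edge_link(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Link eligible pixels whose gradient magnitudes nearly agree.

    A pixel belongs to the output mask when it is eligible and has at
    least one adjacent eligible pixel (4- or 8-neighborhood per
    ``cfg.connectivity``) whose Sobel gradient magnitude differs from its
    own by at most ``cfg.link_threshold``.  Isolated eligible pixels are
    not linked.
    """
    img = as_gray_image(img)
    elig = eligibility_mask(img, cfg)
    grad = gradient_magnitude(img)
    offsets = _OFFSETS_8 if cfg.connectivity == 8 else _OFFSETS_4
    linked = np.zeros_like(elig)
    for dy, dx in offsets:
        nb_elig = _shifted(elig, dy, dx, False)
        nb_grad = _shifted(grad, dy, dx, np.inf)
        linked |= elig & nb_elig & (np.abs(grad - nb_grad) <= cfg.link_threshold)
    return linked


def suppress_dark(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Lift low-brightness pixels to 255.

    Every pixel with value at or below ``cfg.dark_cutoff`` (inclusive;
    default 40) becomes 255, all others are untouched.  Idempotent.
    """
    out = as_gray_image(img)
    out[out <= cfg.dark_cutoff] = 255
    return out


# ---------------------------------------------------------------------------
# morphology and filtering


def _disk(radius: int) -> np.ndarray:
    return morphology.disk(radius)


def morph_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disc of ``radius``."""
    return morphology.closing(np.asarray(mask, dtype=bool), _disk(radius))


def dilate_then_open(mask: np.ndarray, dilate_radius: int, open_radius: int) -> np.ndarray:
    """Dilate to reconnect broken boundary lines, then open to restore size
    and drop sub-element specks."""
    m = morphology.dilation(np.asarray(mask, dtype=bool), _disk(dilate_radius))
    return morphology.opening(m, _disk(open_radius))


def butterworth_smooth(img: np.ndarray, order: int, cutoff: float) -> np.ndarray:
    """Frequency-domain Butterworth low-pass.

    Transfer gain ``1 / (1 + (D/D0)**(2*order))`` where D is the radial
    frequency as a fraction of Nyquist and D0 = ``cutoff``.  The DC gain is
    exactly 1, so constant images pass unchanged; the output is clipped and
    rounded back to uint8.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be a fraction of Nyquist in (0, 1)")
    if order < 1:
        raise ValueError("order must be >= 1")
    f = np.asarray(as_gray_image(img), dtype=np.float64)
    fy = np.fft.fftfreq(f.shape[0])[:, None] / 0.5  # fraction of Nyquist
    fx = np.fft.fftfreq(f.shape[1])[None, :] / 0.5
    d = np.hypot(fy, fx)
    gain = 1.0 / (1.0 + (d / cutoff) ** (2 * order))
    smoothed = np.fft.ifft2(np.fft.fft2(f) * gain).real
    return np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)


def canny_boundaries(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Canny boundary mask (Gaussian smoothing, gradient, non-maximum
    suppression, hysteresis) on the brightness image scaled to [0, 1]."""
    f = np.asarray(as_gray_image(img), dtype=np.float64) / 255.0
    return feature.canny(
        f,
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
    )


# ---------------------------------------------------------------------------
# labeling and object selection


def grassfire_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling by fire-front propagation.

    Scans the mask in raster order; each unvisited foreground pixel seeds a
    new label which is spread breadth-first to its connected neighbors, so
    labels are dense (1..n) and ordered by first raster encounter.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    fg = np.asarray(mask, dtype=bool)
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    h, w = fg.shape
    labels = np.zeros(fg.shape, dtype=np.int32)
    current = 0
    for r, c in np.argwhere(fg):
        if labels[r, c]:
            continue
        current += 1
        labels[r, c] = current
        front = deque([(int(r), int(c))])
        while front:
            y, x = front.popleft()
            for dy, dx in offsets:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not labels[ny, nx]:
                    labels[ny, nx] = current
                    front.append((ny, nx))
    return labels


@dataclass(frozen=True)
class ObjectStats:
    """Geometry of one labeled object (bbox is half-open, (row, col) order)."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # top, left, bottom, right
    density: float                   # area / bbox area
    centroid: tuple[float, float]

    @classmethod
    def from_mask(cls, label: int, obj: np.ndarray) -> "ObjectStats":
        rows, cols = np.nonzero(obj)
        top, bottom = int(rows.min()), int(rows.max()) + 1
        left, right = int(cols.min()), int(cols.max()) + 1
        area = int(rows.size)
        return cls(
            label=label,
            area=area,
            bbox=(top, left, bottom, right),
            density=area / ((bottom - top) * (right - left)),
            centroid=(float(rows.mean()), float(cols.mean())),
        )


def object_stats(labels: np.ndarray) -> list[ObjectStats]:
    """Per-object geometry for every positive label, in label order."""
    out = []
    for k in range(1, int(labels.max()) + 1):
        obj = labels == k
        if obj.any():
            out.append(ObjectStats.from_mask(k, obj))
    return out


def select_tumor_object(labels: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Pick the lesion among labeled boundary objects.

    Each object's enclosed interior is filled, then objects are discarded
    when too small (``min_area``), too sparse (``min_density`` on the filled
    object), or when their bounding box enters the ``lens_margin`` border
    band (the transducer lens and the sector frame always touch the border
    of a standardized frame).  Of the survivors the densest object wins,
    ties going to the larger one.  Returns the filled mask of the winner, or
    an all-false mask when nothing survives ("no tumor found").
    """
    h, w = labels.shape
    best_key: tuple[float, int] | None = None
    best_mask: np.ndarray | None = None
    for k in range(1, int(labels.max()) + 1):
        obj = labels == k
        if not obj.any():
            continue
        filled = ndimage.binary_fill_holes(obj)
        st = ObjectStats.from_mask(k, filled)
        top, left, bottom, right = st.bbox
        if (
            top < cfg.lens_margin
            or left < cfg.lens_margin
            or bottom > h - cfg.lens_margin
            or right > w - cfg.lens_margin
        ):
            continue
        if st.area < cfg.min_area or st.density < cfg.min_density:
            continue
        key = (st.density, st.area)
        if best_key is None or key > best_key:
            best_key, best_mask = key, filled
    if best_mask is None:
        return np.zeros(labels.shape, dtype=bool)
    return best_mask


# ---------------------------------------------------------------------------
# full chain


def extract_object_from_mask(candidate: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Shared tail of both extraction chains.

    Closes the candidate mask, smooths its 0/255 rendering with the
    Butterworth low-pass, traces boundaries with Canny, reconnects and
    cleans them with dilation + opening, labels the boundary objects with
    GrassFire, and selects the dense interior-filled lesion object.
    """
    closed = morph_close(candidate, cfg.close_radius)
    return _trace_and_select(closed, cfg)


def _trace_and_select(candidate: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    rendered = candidate.astype(np.uint8) * 255
    smoothed = butterworth_smooth(rendered, cfg.butterworth_order, cfg.butterworth_cutoff)
    boundaries = canny_boundaries(smoothed, cfg)
    boundaries = dilate_then_open(boundaries, cfg.dilate_radius, cfg.open_radius)
    labels = grassfire_label(boundaries, cfg.connectivity)
    return select_tumor_object(labels, cfg)


def extract_gist(img: np.ndarray, cfg: ExtractionConfig | None = None) -> np.ndarray:
    """Run the full GIST-extraction chain on a gray image.

    Returns the filled lesion mask; an all-false mask means "no tumor
    found".  Deterministic for a fixed input and configuration.
    """
    cfg = cfg or ExtractionConfig()
    img = as_gray_image(img)
    linked = edge_link(img, cfg)
    # Dark-pixel lift: brightness <= dark_cutoff becomes 255.  Applied to
    # the lesion area, i.e. to dark pixels enclosed by the linked set —
    # lifting every dark pixel would pull the acoustic background in.
    lifted_dark = suppress_dark(img, cfg) != img  # pixels the lift affected
    closed = morph_close(linked, cfg.close_radius)
    enclosed = ndimage.binary_fill_holes(closed) & ~closed
    candidate = closed | (enclosed & lifted_dark)
    return _trace_and_select(candidate, cfg)
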