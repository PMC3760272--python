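"""Lipoma extraction from endosonograms.

A lipoma is hyperechoic — a bright, well-demarcated lesion — so the
front end of its extraction chain is brightness-based rather than
gradient-based: the brightness distribution may be regulated by global
histogram equalization, then every pixel below the lipoma brightness floor
(``dark_zero_cutoff``, default 75, the lowest brightness observed inside a
lipoma) is set to 0.  Pixels left nonzero form the candidate foreground
mask, which then goes through the same noise-removal / boundary-tracing /
object-selection tail as the GIST chain.

By default the brightness floor is applied to the raw image and
equalization is skipped (``equalize_first=False``): on frames whose
histogram is dominated by the dark acoustic background, global
equalization stretches that background across the output range and lifts
most of it above the fixed floor, so nothing separable is left for the
threshold to do.  On tissue-dominated frames where the floor needs
per-image normalization, set ``equalize_first=True`` to equalize before
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .gist_extract import ExtractionConfig, extract_object_from_mask
from .image_io import as_gray_image

__all__ = ["LipomaConfig", "equalize_histogram", "zero_dark", "extract_lipoma"]


@dataclass
class LipomaConfig(ExtractionConfig):
    """GIST-chain parameters plus the lipoma-specific front end."""

    dark_zero_cutoff: int = 75   # brightness < cutoff is zeroed (strict)
    equalize_first: bool = False  # equalize before thresholding

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 <= self.dark_zero_cutoff <= 255:
            raise ValueError("dark_zero_cutoff must be in [0, 255]")

    @classmethod
    def from_dict(cls, d: dict) -> "LipomaConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown lipoma config keys: {sorted(unknown)}")
        return cls(**d)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit image.

    The classical integer mapping ``v -> round(255 * (cdf(v) - cdf_min) /
    (n - cdf_min))`` where ``cdf`` is the cumulative brightness histogram
    and ``cdf_min`` its smallest nonzero value.  The mapping is monotone
    non-decreasing; a single-level image is returned unchanged.
    """
    img = as_gray_image(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return img
    cdf_min = cdf[occupied[0]]
    n = img.size
    lut = np.rint(255.0 * (cdf - cdf_min) / (n - cdf_min)).clip(0, 255).astype(np.uint8)
    return lut[img]


def zero_dark(img: np.ndarray, cfg: LipomaConfig) -> np.ndarray:
    """Zero every pixel strictly below the lipoma brightness floor.

    A pixel at exactly ``dark_zero_cutoff`` is retained.  Idempotent.
    """
    out = as_gray_image(img)
    out[out < cfg.dark_zero_cutoff] = 0
    return out


def extract_lipoma(img: np.ndarray, cfg: LipomaConfig | None = None) -> np.ndarray:
    """Run the full lipoma-extraction chain on a gray image.

    Returns the filled lesion mask; an all-false mask means "no tumor
    found".  Deterministic for a fixed input and configuration.
    """
    cfg = cfg or LipomaConfig()
    img = as_gray_image(img)
    work = equalize_histogram(img) if cfg.equalize_first else img
    work = zero_dark(work, cfg)
    candidate = work > 0
    return extract_object_from_mask(candidate, cfg)
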