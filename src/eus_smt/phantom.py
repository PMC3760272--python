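"""Synthetic EUS-like phantoms with ground truth.

Clinical endosonograms cannot ship with the package, so extraction and
classification are exercised end-to-end on synthetic phantoms that emulate
the features the pipelines key on:

* a dark acoustic background filling the frame (clipped-Gaussian speckle);
* a central near-black transducer disc (the "lens" object);
* a bright boundary echo — a 2 px rim around the lesion;
* an elliptical lesion whose interior speckle is moment-matched so that
  the realized masked mean and standard deviation hit the requested
  targets to within +/-3 brightness levels.

The speckle is clipped Gaussian rather than Rayleigh: the classifier
consumes only the first two moments of the region, so the distribution
family is immaterial, and clipped-Gaussian targets can be matched exactly
by an iterative affine correction.  Everything is deterministic per seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from skimage import draw

__all__ = [
    "TumorClass",
    "PhantomSpec",
    "PhantomSample",
    "CLASS_BANDS",
    "speckle_feasible",
    "generate_phantom",
    "generate_cohort",
]


class TumorClass(str, enum.Enum):
    """Ground-truth lesion class of a phantom."""

    CYST = "cyst"
    GIST = "gist"
    LIPOMA = "lipoma"


#: Per-class (mean, sd) brightness bands the cohort generator draws from,
#: aligned with the plateaus of the membership functions: cysts are dark
#: and smooth, GISTs mid-gray with moderate speckle, lipomas bright with
#: strong speckle.  These are fuzzy-system working bands, not claims about
#: absolute clinical echogenicity values.
CLASS_BANDS: dict[TumorClass, tuple[tuple[float, float], tuple[float, float]]] = {
    TumorClass.CYST: ((10.0, 50.0), (5.0, 50.0)),
    TumorClass.GIST: ((58.0, 72.0), (55.0, 80.0)),
    TumorClass.LIPOMA: ((80.0, 200.0), (90.0, 130.0)),
}


class UnrealizableSpeckleError(ValueError):
    """Raised when no [0, 255] pixel population can have the target moments."""


def speckle_feasible(mean: float, sd: float, margin: float = 1.0) -> bool:
    """Whether (mean, sd) is attainable for values confined to [0, 255].

    The Bhatia-Davis bound caps the variance of any [0, 255] distribution
    at ``mean * (255 - mean)``; ``margin`` < 1 demands headroom below it.
    """
    if not 0 <= mean <= 255 or sd < 0:
        return False
    return sd * sd <= margin * mean * (255.0 - mean)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom frame."""

    tumor_class: TumorClass
    center: tuple[float, float]        # (row, col) of the lesion
    axes: tuple[float, float]          # semi-axes (a, b) in px
    rotation_deg: float = 0.0
    interior_mean: float = 65.0
    interior_sd: float = 20.0
    width: int = 256
    height: int = 256
    rim_brightness: int = 200
    rim_thickness: int = 2
    background_mean: float = 18.0
    background_sd: float = 6.0
    transducer_radius: int = 16
    lens_margin: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PhantomSample:
    """A generated phantom with its ground truth."""

    image: np.ndarray
    mask: np.ndarray
    tumor_class: TumorClass
    spec: PhantomSpec


def _matched_speckle(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    tol: float = 0.5,
    max_iter: int = 200,
) -> np.ndarray:
    """Clipped-Gaussian values whose sample mean/SD match the targets.

    Alternates clipping to [0, 255] with an affine re-standardization until
    the clipped sample's moments are within ``tol`` of the targets; heavy
    clipping drives the sample toward the bimodal 0/255 shape that extreme
    (mean, sd) pairs require.
    """
    vals = rng.normal(mean, sd, size=n)
    for _ in range(max_iter):
        clipped = np.clip(vals, 0.0, 255.0)
        m, s = clipped.mean(), clipped.std()
        if abs(m - mean) <= tol and abs(s - sd) <= tol:
            return clipped
        vals = (clipped - m) * (sd / max(s, 1e-9)) + mean
    raise UnrealizableSpeckleError(
        f"unrealizable speckle spec: mean={mean}, sd={sd} not matched within "
        f"{tol} after {max_iter} iterations"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns (image, ground-truth lesion mask).

    The mask is the exact rasterized lesion ellipse (rim excluded).
    Deterministic per ``spec.seed``.
    """
    h, w = spec.height, spec.width
    if spec.interior_sd > 0 and not speckle_feasible(spec.interior_mean, spec.interior_sd):
        raise UnrealizableSpeckleError(
            f"unrealizable speckle spec: sd={spec.interior_sd} exceeds the "
            f"variance bound for mean={spec.interior_mean} on [0, 255]"
        )
    rng = np.random.default_rng(spec.seed)

    img = np.clip(
        np.rint(rng.normal(spec.background_mean, spec.background_sd, size=(h, w))),
        0,
        255,
    ).astype(np.uint8)

    # transducer lens: near-black disc at the frame center
    rr, cc = draw.disk((h / 2, w / 2), spec.transducer_radius, shape=(h, w))
    img[rr, cc] = 2

    a, b = spec.axes
    rot = math.radians(spec.rotation_deg)
    rr, cc = draw.ellipse(*spec.center, a + spec.rim_thickness, b + spec.rim_thickness,
                          shape=(h, w), rotation=rot)
    rim_and_interior = np.zeros((h, w), dtype=bool)
    rim_and_interior[rr, cc] = True
    rr, cc = draw.ellipse(*spec.center, a, b, shape=(h, w), rotation=rot)
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True

    rows, cols = np.nonzero(rim_and_interior)
    if (
        rows.size == 0
        or rows.min() < spec.lens_margin
        or cols.min() < spec.lens_margin
        or rows.max() >= h - spec.lens_margin
        or cols.max() >= w - spec.lens_margin
    ):
        raise ValueError("lesion ellipse (with rim) must clear the border margin")

    img[rim_and_interior & ~mask] = spec.rim_brightness
    n = int(mask.sum())
    if spec.interior_sd == 0:
        img[mask] = int(round(spec.interior_mean))
    else:
        vals = _matched_speckle(rng, n, spec.interior_mean, spec.interior_sd)
        img[mask] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
    return img, mask


def generate_cohort(
    n_per_class: int,
    seed: int,
    width: int = 256,
    height: int = 256,
) -> list[PhantomSample]:
    """A balanced cohort of phantoms, ``n_per_class`` per lesion class.

    Lesion geometry (offset from frame center, semi-axes, rotation) and
    interior (mean, sd) are drawn uniformly from documented ranges; (mean,
    sd) pairs violating the clipped-range variance bound (with a 0.9
    safety margin) are redrawn.  Deterministic per ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for cls in (TumorClass.CYST, TumorClass.GIST, TumorClass.LIPOMA):
        (m_lo, m_hi), (s_lo, s_hi) = CLASS_BANDS[cls]
        for _ in range(n_per_class):
            while True:
                mean = rng.uniform(m_lo, m_hi)
                sd = rng.uniform(s_lo, s_hi)
                if speckle_feasible(mean, sd, margin=0.81):  # 0.9 margin on sd
                    break
            angle = rng.uniform(0.0, 2.0 * math.pi)
            offset = rng.uniform(60.0, 78.0)
            center = (
                height / 2 + offset * math.sin(angle),
                width / 2 + offset * math.cos(angle),
            )
            axes = (rng.uniform(20.0, 36.0), rng.uniform(20.0, 36.0))
            rotation = rng.uniform(0.0, 180.0)
            spec = PhantomSpec(
                tumor_class=cls,
                center=center,
                axes=axes,
                rotation_deg=rotation,
                interior_mean=mean,
                interior_sd=sd,
                width=width,
                height=height,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, mask = generate_phantom(spec)
            samples.append(PhantomSample(image=image, mask=mask, tumor_class=cls, spec=spec))
    return samples
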