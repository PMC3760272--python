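"""Fuzzy GIST / non-GIST classification from region brightness statistics.

The classifier consumes two crisp features of a tumor region — the mean
brightness (MEAN) and the population standard deviation of brightness (SD)
— and runs a small Mamdani system over them:

* MEAN is fuzzified into three linguistic sets A1 (dark), A2 (mid), A3
  (bright) and SD into B1 (smooth), B2 (mid), B3 (speckled).  All six are
  piecewise-linear (shoulder trapezoids at the edges, a triangle in the
  middle) with breakpoints fixed from ROC analysis of clinical frames:
  MEAN 0/55/65, 55/65/75, 65/75/255 and SD 0/65/75, 65/75/85, 75/85/255.
  Adjacent sets are complementary, so each family sums to exactly 1
  everywhere on [0, 255].
* Nine IF-THEN rules map every (Ai, Bj) pair onto an output set G1
  (cyst-like), G2 (GIST-like) or G3 (lipoma-like); rule strength is the
  minimum of its two antecedent degrees and each consequent's activation
  the maximum over its rules (min-max reasoning).
* The activations clip their output sets (triangles on the score interval
  [1, 5]); the clipped sets are aggregated by pointwise maximum and
  collapsed to the crisp score Wz by the centroid (center of gravity) of
  the aggregate, evaluated on a uniform sample grid.
* Wz in [1, 2) calls a non-GIST cyst, [2, 4) a GIST, and [4, 5] a
  non-GIST lipoma.  The shared band edges (2 and 4) are resolved so that
  Wz = 2 keeps the clinically cautious GIST call; both cuts are
  configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "TumorLabel",
    "FuzzySet",
    "FuzzyConfig",
    "RegionStats",
    "ClassificationResult",
    "region_stats",
    "build_input_sets",
    "build_output_sets",
    "fire_rules",
    "defuzzify_centroid",
    "classify",
    "classify_stats",
    "classify_region",
    "RULE_TABLE",
]


class TumorLabel(str, enum.Enum):
    """Categorical call of the classifier."""

    GIST = "GIST"
    NON_GIST_CYST = "NON_GIST_CYST"
    NON_GIST_LIPOMA = "NON_GIST_LIPOMA"


#: Consequent index (1-3 for G1-G3) for each (Ai, Bj) antecedent pair.
RULE_TABLE: dict[tuple[int, int], int] = {
    (1, 1): 1, (1, 2): 1, (1, 3): 1,
    (2, 1): 1, (2, 2): 2, (2, 3): 2,
    (3, 1): 2, (3, 2): 2, (3, 3): 3,
}


@dataclass(frozen=True)
class FuzzySet:
    """A named piecewise-linear membership function.

    ``points`` are (x, degree) breakpoints with strictly increasing x;
    outside the breakpoint range the degree continues at the end values
    (the end degrees are 0 for triangles, so they vanish off-support, and
    1 for shoulders, which is moot because the feature domain ends there).
    """

    name: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        if len(xs) < 2 or any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError(f"{self.name}: breakpoint x must be strictly increasing")
        if any(not 0 <= p[1] <= 1 for p in self.points):
            raise ValueError(f"{self.name}: degrees must lie in [0, 1]")

    def __call__(self, x):
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return np.interp(x, xs, ys, left=ys[0], right=ys[-1])


def _three_sets(prefix: str, breaks) -> tuple[FuzzySet, FuzzySet, FuzzySet]:
    (l1, l2, l3), (m1, m2, m3), (r1, r2, r3) = (tuple(map(float, b)) for b in breaks)
    low = FuzzySet(prefix + "1", ((l1, 1.0), (l2, 1.0), (l3, 0.0)))
    mid = FuzzySet(prefix + "2", ((m1, 0.0), (m2, 1.0), (m3, 0.0)))
    high = FuzzySet(prefix + "3", ((r1, 0.0), (r2, 1.0), (r3, 1.0)))
    return low, mid, high


@dataclass
class FuzzyConfig:
    """Membership-function geometry and inference settings."""

    mean_breakpoints: tuple = ((0, 55, 65), (55, 65, 75), (65, 75, 255))
    sd_breakpoints: tuple = ((0, 65, 75), (65, 75, 85), (75, 85, 255))
    #: Output-set triangle vertices on the score domain.  Chosen so that
    #: each single-consequent centroid lands inside its decision band —
    #: G1 alone -> 5/3 (cyst), G2 alone -> 3 (GIST), G3 alone -> 13/3
    #: (lipoma) — and symmetric, so a clipped set keeps its centroid at
    #: the peak regardless of activation level (an asymmetric edge set
    #: drags Wz around as its activation varies).
    output_vertices: tuple = ((1, 5 / 3, 7 / 3), (1, 3, 5), (11 / 3, 13 / 3, 5))
    domain: tuple[float, float] = (1.0, 5.0)
    resolution: int = 1001
    cyst_below: float = 2.0    # Wz < cyst_below -> cyst
    lipoma_from: float = 4.0   # Wz >= lipoma_from -> lipoma

    def __post_init__(self) -> None:
        if self.resolution < 100:
            raise ValueError("resolution must be >= 100")
        if not self.domain[0] < self.cyst_below <= self.lipoma_from < self.domain[1]:
            raise ValueError("decision cuts must be ordered inside the score domain")

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown fuzzy config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("mean_breakpoints", "sd_breakpoints", "output_vertices"):
            if key in d:
                d[key] = tuple(tuple(v) for v in d[key])
        if "domain" in d:
            d["domain"] = tuple(d["domain"])
        return cls(**d)


def build_input_sets(cfg: FuzzyConfig | None = None):
    """The six input membership functions (A1, A2, A3), (B1, B2, B3)."""
    cfg = cfg or FuzzyConfig()
    return _three_sets("A", cfg.mean_breakpoints), _three_sets("B", cfg.sd_breakpoints)


def build_output_sets(cfg: FuzzyConfig | None = None):
    """The three output sets G1-G3 as triangles on the score domain."""
    cfg = cfg or FuzzyConfig()
    out = []
    for i, (a, b, c) in enumerate(cfg.output_vertices, start=1):
        pts = [(float(a), 0.0), (float(b), 1.0), (float(c), 0.0)]
        if a == b:      # left shoulder: peak at the domain edge
            pts = [(float(b), 1.0), (float(c), 0.0)]
        elif b == c:    # right shoulder
            pts = [(float(a), 0.0), (float(b), 1.0)]
        out.append(FuzzySet(f"G{i}", tuple(pts)))
    return tuple(out)


@dataclass(frozen=True)
class RegionStats:
    """Brightness statistics of a tumor region."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not 0 <= self.mean <= 255:
            raise ValueError("mean must lie in [0, 255]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


class EmptyRegionError(ValueError):
    """Raised when statistics are requested over an empty mask."""


class NoRuleFiredError(ValueError):
    """Raised when no inference rule has positive strength."""


def region_stats(img: np.ndarray, mask: np.ndarray) -> RegionStats:
    """MEAN and population SD of brightness over the masked pixels."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    vals = img[mask]
    if vals.size == 0:
        raise EmptyRegionError("empty region: mask selects no pixels")
    vals = vals.astype(np.float64)
    return RegionStats(mean=float(vals.mean()), sd=float(vals.std()), n_pixels=int(vals.size))


def fire_rules(a_degrees, b_degrees) -> np.ndarray:
    """Min-max inference over the nine-rule base.

    Rule strength = min(antecedent degrees); each consequent's activation =
    max over the rules concluding it.  Returns activations for (G1, G2, G3).
    """
    a = np.asarray(a_degrees, dtype=np.float64)
    b = np.asarray(b_degrees, dtype=np.float64)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("expected three membership degrees per feature")
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("membership degrees must lie in [0, 1]")
    act = np.zeros(3)
    for (i, j), k in RULE_TABLE.items():
        strength = min(a[i - 1], b[j - 1])
        act[k - 1] = max(act[k - 1], strength)
    return act


def defuzzify_centroid(
    activations,
    output_sets=None,
    domain: tuple[float, float] = (1.0, 5.0),
    resolution: int = 1001,
) -> float:
    """Centroid (center of gravity) of the clipped, max-aggregated output.

    The aggregate membership ``mu(x) = max_k min(act_k, G_k(x))`` is
    sampled at ``resolution`` uniform points on the score domain and the
    centroid ``sum(w * mu * x) / sum(w * mu)`` returned, with trapezoid
    end-weights (w = 1/2 at the two domain ends) so the sampled centroid
    converges quadratically to the continuous center of gravity.
    """
    act = np.asarray(activations, dtype=np.float64)
    if np.any((act < 0) | (act > 1)):
        raise ValueError("activations must lie in [0, 1]")
    if resolution < 100:
        raise ValueError("resolution must be >= 100")
    if output_sets is None:
        output_sets = build_output_sets()
    if not np.any(act > 0):
        raise NoRuleFiredError("no rule fired: all activations are zero")
    xs = np.linspace(domain[0], domain[1], resolution)
    mu = np.zeros_like(xs)
    for a_k, g_k in zip(act, output_sets):
        np.maximum(mu, np.minimum(a_k, g_k(xs)), out=mu)
    w = np.ones_like(xs)
    w[0] = w[-1] = 0.5
    wmu = w * mu
    return float((wmu * xs).sum() / wmu.sum())


def classify(wz: float, cfg: FuzzyConfig | None = None) -> TumorLabel:
    """Map a defuzzified score onto the categorical call."""
    cfg = cfg or FuzzyConfig()
    lo, hi = cfg.domain
    if not lo - 1e-9 <= wz <= hi + 1e-9:
        raise ValueError(f"Wz={wz} outside the score domain [{lo}, {hi}]")
    if wz < cfg.cyst_below:
        return TumorLabel.NON_GIST_CYST
    if wz < cfg.lipoma_from:
        return TumorLabel.GIST
    return TumorLabel.NON_GIST_LIPOMA


@dataclass(frozen=True)
class ClassificationResult:
    """Full provenance of one classification."""

    stats: RegionStats
    a_degrees: tuple[float, float, float]
    b_degrees: tuple[float, float, float]
    activations: tuple[float, float, float]
    wz: float
    label: TumorLabel

    def to_dict(self) -> dict:
        return {
            "mean": self.stats.mean,
            "sd": self.stats.sd,
            "n_pixels": self.stats.n_pixels,
            "a_degrees": list(self.a_degrees),
            "b_degrees": list(self.b_degrees),
            "activations": list(self.activations),
            "wz": self.wz,
            "label": self.label.value,
        }


def classify_stats(stats: RegionStats, cfg: FuzzyConfig | None = None) -> ClassificationResult:
    """Classify a region from its (mean, sd) statistics alone."""
    cfg = cfg or FuzzyConfig()
    a_sets, b_sets = build_input_sets(cfg)
    out_sets = build_output_sets(cfg)
    a = np.array([s(stats.mean) for s in a_sets])
    b = np.array([s(stats.sd) for s in b_sets])
    act = fire_rules(a, b)
    wz = defuzzify_centroid(act, out_sets, cfg.domain, cfg.resolution)
    return ClassificationResult(
        stats=stats,
        a_degrees=tuple(float(v) for v in a),
        b_degrees=tuple(float(v) for v in b),
        activations=tuple(float(v) for v in act),
        wz=wz,
        label=classify(wz, cfg),
    )


def classify_region(
    img: np.ndarray, mask: np.ndarray, cfg: FuzzyConfig | None = None
) -> ClassificationResult:
    """End-to-end call: region statistics -> fuzzification -> rules ->
    centroid defuzzification -> Table-style decision bands."""
    return classify_stats(region_stats(img, mask), cfg)
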