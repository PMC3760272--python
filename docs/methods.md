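# Methods

`eus-smt` analyzes 8-bit grayscale endosonograms of gastric submucosal
tumors (SMTs). It has three computational parts: two rule-based
segmentation chains that extract the lesion region from a standardized
EUS frame (one tuned to the gradient-rich, intermediate-echogenicity
appearance of a gastrointestinal stromal tumor, one to the bright,
well-demarcated appearance of a lipoma), and a Mamdani fuzzy system that
classifies a tumor region as GIST or non-GIST (cyst / lipoma) from two
crisp features of the region: the mean brightness (MEAN) and the
population standard deviation of brightness (SD).

## GIST extraction

The chain assumes the standardized EUS appearance: a dark acoustic
background, bright boundary echoes around structures, the transducer
appearing as a near-black disc, and a speckled lesion of intermediate
brightness. Stages, with defaults:

1. **Boundary-line suppression.** Pixels below `bright_floor = 30` are
   ineligible. Boundary lines of extreme brightness can additionally be
   removed with an optional `bright_ceiling`; it is disabled by default
   because no defensible value is known for the high side, and the
   border-exclusion rule in object selection already handles the frame
   artifacts the ceiling would target.
2. **Edge linking.** A Sobel 3×3 gradient magnitude is computed; an
   eligible pixel links to an adjacent eligible pixel (8-connectivity)
   when their gradient magnitudes differ by at most
   `link_threshold = 130`. The linked set is the candidate region.
   The linking criterion is read as a comparison of gradient
   *magnitudes* (not raw brightness differences); this is flagged as an
   interpretation, since the defining notation is ambiguous.
3. **Dark-pixel lift.** Brightness at or below `dark_cutoff = 40`
   (inclusive) is raised to 255. As a standalone operation the lift is
   global and idempotent. Inside the pipeline it is applied to the
   lesion area only: dark pixels *enclosed by* the (closed) linked set
   join the candidate region. A global lift would raise the acoustic
   background — which is also ≤ 40 — into the foreground and merge
   lesion, rim and background into one border-touching object.
4. **Closing** with a disc of radius 2 fills pinholes and small gaps.
5. **Butterworth low-pass.** The candidate mask, rendered 0/255, is
   smoothed in the frequency domain with gain
   `1 / (1 + (D/D0)^(2n))`, `n = 2`, `D0 = 0.3` of Nyquist; DC gain is
   exactly 1, the result is rounded back to [0, 255]. This rounds off
   the jagged mask boundary before tracing.
6. **Canny boundary extraction** (σ = 1.4, hysteresis 0.1/0.3 on the
   [0, 1]-scaled image) yields thin closed contours.
7. **Dilation (r = 2) then opening (r = 2)** reconnects broken contour
   segments and drops specks smaller than the element. Note that
   opening after dilation cannot shrink a surviving object back below
   its dilated size — `open(dilate(X)) = dilate(close(X))` — so the
   traced boundary sits 2–3 px outside the true edge; this is the main
   reason extraction IoU plateaus around 0.75 rather than 1.0.
8. **GrassFire labeling.** Connected components are labeled by
   breadth-first fire-front propagation in raster-scan order, so labels
   are dense and ordered by first encounter. (An independent flood-fill
   implementation serves as the oracle in tests.)
9. **Object selection.** Each labeled contour object is interior-filled;
   objects are discarded if the filled area is below `min_area = 200`
   px, if the fill density (area / bounding-box area) is below
   `min_density = 0.4` (curvilinear artifacts), or if the bounding box
   enters a `lens_margin = 5` px border band (the transducer disc and
   sector frame always touch the border of a standardized frame — a
   documented heuristic). The densest survivor wins, ties going to the
   larger area. An empty result means "no tumor found".

## Lipoma extraction

A lipoma is hyperechoic with clear boundaries, so the front end is a
brightness threshold: pixels strictly below `dark_zero_cutoff = 75` (the
lowest brightness observed inside a lipoma) are set to 0, and the
remaining nonzero pixels form the candidate mask, which goes through
stages 4–9 above unchanged.

Global histogram equalization (the classical integer CDF mapping
`v → round(255·(cdf(v) − cdf_min)/(n − cdf_min))`) is available ahead of
the threshold via `equalize_first=True`, for tissue-dominated frames
whose brightness distribution needs per-image normalization before a
fixed floor is meaningful. It is **off by default**: on frames whose
histogram is dominated by the dark acoustic background — every phantom,
and any water-filled-lumen frame — equalization stretches that dark mass
across the output range, so the fixed floor degenerates into a ~29th
percentile cut *inside the background* and the threshold no longer
separates anything. The mapping itself is monotone and idempotent up to
quantization (≤ 2 levels of drift on reapplication), which the tests
check.

## Fuzzy classification

MEAN is fuzzified by three piecewise-linear sets with breakpoints
(0, 55, 65), (55, 65, 75), (65, 75, 255) — a left shoulder, a triangle,
a right shoulder — and SD likewise with (0, 65, 75), (65, 75, 85),
(75, 85, 255). These interval constants originate from ROC analysis of
clinical frames and are treated as fixed. Adjacent sets are
complementary, so each family sums to exactly 1 on [0, 255] (tested at
all 256 integer levels to 1e-12).

Nine rules map the antecedent pairs to output sets G1 (cyst-like), G2
(GIST-like), G3 (lipoma-like):

| | B1 | B2 | B3 |
|---|---|---|---|
| **A1** | G1 | G1 | G1 |
| **A2** | G1 | G2 | G2 |
| **A3** | G2 | G2 | G3 |

Rule strength is the minimum of the two antecedent degrees; consequent
activation is the maximum over its rules (min–max reasoning). The
activations clip their output sets; the pointwise-maximum aggregate is
collapsed to the score Wz by its center of gravity, and Wz ∈ [1, 2)
calls a cyst, [2, 4) a GIST, [4, 5] a lipoma. The shared band edges are
resolved half-open with Wz = 2 kept as GIST — the clinically cautious
call — and Wz = 4 as lipoma; both cuts are configurable.

**Output-set geometry.** The decision bands constrain the output sets
only through their single-consequent centroids: G1 alone must defuzzify
into the cyst band, G2 into the GIST band, G3 into the lipoma band. The
shipped vertices are *symmetric* triangles (1, 5/3, 7/3), (1, 3, 5),
(11/3, 13/3, 5), giving single-set centroids 5/3, 3 and 13/3. Symmetry
matters: a clipped symmetric triangle keeps its centroid at the peak for
every activation level, whereas an edge-anchored shoulder set drags the
centroid with its activation, which makes Wz visibly non-monotone in the
features (dips of 0.03–0.15 around the A1/A2 crossover). With symmetric
sets, Wz is non-decreasing in MEAN at fixed SD (and vice versa) whenever
the fixed feature sits at full membership of one set; inside the
membership blending bands, min–max inference still produces small
crossover dips (≤ ~0.11 in Wz, bounded by a test) because two adjacent
antecedent sets feeding the same consequent exchange dominance. This is
a structural property of Mamdani max-aggregation, not a numerical
artifact.

**Numerics.** SD is the population (divide-by-n) standard deviation —
a whole-region descriptor, not a sample estimate. The centroid is
evaluated on a uniform grid of 1001 points over [1, 5] with trapezoid
end-weights (½ at the domain ends); the end-weighting removes an O(h)
endpoint bias and brings the sampled centroid within ~2×10⁻⁶ of a
million-point reference, comfortably inside the 10⁻³ agreement the tests
demand. All activations at zero is an error ("no rule fired"), as is an
empty region.

## Synthetic phantoms

Clinical frames cannot ship with the package, so the generator renders
the features the chains key on: a dark speckled background (mean 18,
SD 6), a near-black transducer disc (radius 16 px) at the frame center,
a 2 px bright rim (level 200) around an elliptical lesion, and a lesion
interior of clipped-Gaussian speckle. The interior sample is iteratively
re-standardized and re-clipped until its realized mean and SD are within
0.5 of target (±3 after integer rounding is the guaranteed envelope);
targets violating the Bhatia–Davis variance bound
`sd² ≤ mean·(255 − mean)` for [0, 255]-confined values are rejected as
unrealizable. The speckle family is Gaussian, not Rayleigh, because the
classifier consumes only the first two moments.

The cohort generator draws per class: interior mean and SD uniform from
cyst (10–50, 5–50), GIST (58–72, 55–80), lipoma (80–200, 90–130) —
bands centered on the membership plateaus; pairs violating 0.9× the
variance bound are redrawn deterministically (the lipoma band can exceed
the bound at high mean). Geometry: lesion center offset 60–78 px from
the frame center at a uniform angle, semi-axes 20–36 px, uniform
rotation, which keeps every lesion clear of both the transducer disc and
the 5 px border band. Everything derives from a single seed via one
PCG64 stream.

What the phantoms do *not* model: speckle correlation and point-spread
anisotropy, attenuation and acoustic shadowing, tissue layers and
neighboring anatomy, capsule echoes, probe-contact artifacts. Passing on
phantoms therefore shows the chains implement their specification and
behave sensibly on images with the assumed brightness structure; it is
not evidence of clinical accuracy.

## Evaluation harness

`evaluate` runs the lipoma chain on lipoma frames and the GIST chain on
GIST and cyst frames (cysts share the hypoechoic presentation),
operationalizes "successful extraction" as IoU ≥ 0.5 against ground
truth (configurable; the historical criterion was visual), and reduces
classification to the two-class GIST vs non-GIST question. On a
fixed-seed cohort of 30 phantoms (10 per class, 256×256 px — small
enough that the whole evaluation runs in seconds on one CPU) the
shipped defaults extract 30/30 lesions at IoU ≥ 0.5 (mean IoU ≈ 0.75)
and classify 28–29/30 correctly; the misses are GIST phantoms whose
drawn mean and SD fall in the low corner of the GIST band, where the
membership functions genuinely favor the cyst call.

## Known limitations

- The extracted mask systematically overshoots the true lesion by the
  rim width plus the dilation radius (see stage 7), bounding IoU.
- One lesion per frame; overlapping or border-touching lesions are out
  of scope, as are vendor overlays and DICOM input.
- The fuzzy constants are fixed; no learning, ROC re-estimation, or
  texture features beyond MEAN and SD.
- Wz monotonicity holds exactly only on membership plateaus (above).
- Frequency-domain smoothing makes extraction only approximately
  invariant to padding the frame with background (tested at IoU ≥ 0.95
  after a 16 px pad).
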