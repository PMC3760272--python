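import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from eus_smt.gist_extract import (
    ExtractionConfig,
    butterworth_smooth,
    canny_boundaries,
    dilate_then_open,
    edge_link,
    eligibility_mask,
    extract_gist,
    gradient_magnitude,
    grassfire_label,
    morph_close,
    object_stats,
    select_tumor_object,
    suppress_boundary_lines,
    suppress_dark,
)
from eus_smt.cli import iou


# ---------------------------------------------------------------------------
# boundary-line suppression and edge linking


def test_suppress_boundary_lines_keeps_mid_brightness(extraction_cfg):
    img = np.full((16, 16), 128, dtype=np.uint8)
    np.testing.assert_array_equal(suppress_boundary_lines(img, extraction_cfg), img)


def test_suppress_boundary_lines_drops_dark_pixels(extraction_cfg):
    img = np.full((16, 16), 128, dtype=np.uint8)
    img[3, 3] = 10
    out = suppress_boundary_lines(img, extraction_cfg)
    assert out[3, 3] == 0
    assert not eligibility_mask(img, extraction_cfg)[3, 3]


def test_all_dark_image_has_empty_eligibility(extraction_cfg):
    img = np.full((16, 16), 29, dtype=np.uint8)
    assert not eligibility_mask(img, extraction_cfg).any()


def test_bright_ceiling_excludes_bright_boundary_lines():
    cfg = ExtractionConfig(bright_ceiling=200)
    img = np.full((16, 16), 128, dtype=np.uint8)
    img[5, 5] = 240
    assert not eligibility_mask(img, cfg)[5, 5]


def _edge_link_bruteforce(img, cfg):
    """Independent O(n^2-per-pixel) evaluation of the linking rule."""
    elig = (img >= cfg.bright_floor)
    if cfg.bright_ceiling is not None:
        elig &= img <= cfg.bright_ceiling
    grad = gradient_magnitude(img)
    h, w = img.shape
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if cfg.connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    out = np.zeros_like(elig)
    for y in range(h):
        for x in range(w):
            if not elig[y, x]:
                continue
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and elig[ny, nx]:
                    if abs(grad[y, x] - grad[ny, nx]) <= cfg.link_threshold:
                        out[y, x] = True
                        break
    return out


def test_edge_link_matches_bruteforce_oracle(rng, extraction_cfg):
    for connectivity in (4, 8):
        cfg = ExtractionConfig(connectivity=connectivity)
        for _ in range(5):
            img = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
            np.testing.assert_array_equal(
                edge_link(img, cfg), _edge_link_bruteforce(img, cfg)
            )


def test_edge_link_uniform_image_links_all_eligible(extraction_cfg):
    img = np.full((16, 16), 100, dtype=np.uint8)
    assert edge_link(img, extraction_cfg).all()


def test_edge_link_isolated_eligible_pixel_not_linked(extraction_cfg):
    img = np.zeros((16, 16), dtype=np.uint8)
    img[8, 8] = 200  # only eligible pixel, no eligible neighbor
    assert not edge_link(img, extraction_cfg).any()


def test_edge_link_threshold_is_monotone(rng):
    img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
    small = edge_link(img, ExtractionConfig(link_threshold=20))
    large = edge_link(img, ExtractionConfig(link_threshold=500))
    assert np.all(large[small])  # raising Th never unlinks a pixel


# ---------------------------------------------------------------------------
# dark-pixel lift


def test_suppress_dark_threshold_semantics(extraction_cfg):
    img = np.array([[40, 41], [0, 255]], dtype=np.uint8)
    img = np.pad(img, ((0, 6), (0, 6)), constant_values=100)
    out = suppress_dark(img, extraction_cfg)
    assert out[0, 0] == 255   # at the cutoff: lifted (inclusive)
    assert out[0, 1] == 41    # first value above the cutoff: kept
    assert out[1, 0] == 255
    assert out[1, 1] == 255


def test_suppress_dark_idempotent(rng, extraction_cfg):
    img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
    once = suppress_dark(img, extraction_cfg)
    np.testing.assert_array_equal(suppress_dark(once, extraction_cfg), once)


def test_suppress_dark_all_bright_fixed_point(extraction_cfg):
    img = np.full((8, 8), 255, dtype=np.uint8)
    np.testing.assert_array_equal(suppress_dark(img, extraction_cfg), img)


# ---------------------------------------------------------------------------
# morphology


def _brute_dilate(mask, radius):
    offs = np.argwhere(disk(radius)) - radius
    out = np.zeros_like(mask)
    h, w = mask.shape
    for y, x in np.argwhere(mask):
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                out[ny, nx] = True
    return out


def _brute_erode(mask, radius):
    offs = np.argwhere(disk(radius)) - radius
    out = np.zeros_like(mask)
    for y, x in np.argwhere(mask):
        if all(
            0 <= y + dy < mask.shape[0]
            and 0 <= x + dx < mask.shape[1]
            and mask[y + dy, x + dx]
            for dy, dx in offs
        ):
            out[y, x] = True
    return out


def test_morph_close_matches_bruteforce_on_interior_masks(rng):
    # keep foreground clear of the border so boundary conventions are moot
    for _ in range(5):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 4:16] = rng.random((12, 12)) < 0.45
        expected = _brute_erode(_brute_dilate(mask, 1), 1)
        np.testing.assert_array_equal(morph_close(mask, 1), expected)


def test_morph_close_fills_interior_hole():
    mask = np.zeros((16, 16), dtype=bool)
    mask[3:13, 3:13] = True
    mask[8, 8] = False
    assert morph_close(mask, 1)[8, 8]


def test_morph_close_is_extensive(rng):
    mask = np.zeros((20, 20), dtype=bool)
    mask[3:17, 3:17] = rng.random((14, 14)) < 0.4
    closed = morph_close(mask, 2)
    assert np.all(closed[mask])  # closing never removes input foreground


def test_morph_close_empty_mask():
    assert not morph_close(np.zeros((12, 12), dtype=bool), 2).any()


def test_morph_close_merges_one_pixel_gap():
    mask = np.zeros((12, 20), dtype=bool)
    mask[4:8, 3:9] = True
    mask[4:8, 10:16] = True  # one-column gap at x=9
    closed = morph_close(mask, 1)
    assert ndimage.label(closed)[1] == 1


def test_dilate_then_open_reconnects_broken_ring():
    mask = np.zeros((32, 32), dtype=bool)
    rr = np.arange(360)
    ys = (16 + 10 * np.sin(np.radians(rr))).astype(int)
    xs = (16 + 10 * np.cos(np.radians(rr))).astype(int)
    mask[ys, xs] = True
    mask[16, 26] = False  # one-pixel break
    out = dilate_then_open(mask, 1, 1)
    assert ndimage.label(out)[1] == 1


def test_dilate_then_open_removes_isolated_pixel():
    # opening removes features smaller than its element, so the element
    # must exceed the dilated speck for removal
    mask = np.zeros((16, 16), dtype=bool)
    mask[8, 8] = True
    assert not dilate_then_open(mask, 1, 2).any()


def test_dilate_then_open_matches_bruteforce_on_square():
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:30, 10:30] = True  # 20x20 = 400 px
    out = dilate_then_open(mask, 2, 2)
    expected = _brute_dilate(_brute_erode(_brute_dilate(mask, 2), 2), 2)
    np.testing.assert_array_equal(out, expected)
    # growth is bounded by the dilation element
    assert 400 <= out.sum() <= 24 * 24


# ---------------------------------------------------------------------------
# Butterworth low-pass


def test_butterworth_uniform_image_unchanged():
    img = np.full((32, 32), 137, dtype=np.uint8)
    np.testing.assert_array_equal(butterworth_smooth(img, 2, 0.3), img)


def test_butterworth_impulse_matches_transfer_function_oracle():
    img = np.zeros((32, 32), dtype=np.uint8)
    img[16, 16] = 255
    # independent oracle: explicit transfer gain on the impulse spectrum
    fy, fx = np.meshgrid(np.fft.fftfreq(32), np.fft.fftfreq(32), indexing="ij")
    d = np.sqrt(fy**2 + fx**2) / 0.5
    gain = 1.0 / (1.0 + (d / 0.3) ** 4)
    expected = np.fft.ifft2(np.fft.fft2(img.astype(float)) * gain).real
    out = butterworth_smooth(img, 2, 0.3)
    np.testing.assert_allclose(out, np.clip(np.rint(expected), 0, 255), atol=0)
    # total brightness is conserved by the unit DC gain, up to rounding
    assert abs(int(out.sum()) - 255) <= img.size / 2


def test_butterworth_attenuates_nyquist_stripes():
    img = np.zeros((32, 32), dtype=np.uint8)
    img[:, ::2] = 192
    img[:, 1::2] = 64
    out = butterworth_smooth(img, 2, 0.2).astype(float)
    # closed form: stripe amplitude scales by 1/(1+(1/0.2)^4) ~ 1/626
    residual = np.abs(out - 128.0).max()
    assert residual <= 64 / (1 + 5**4) + 1  # within rounding


# ---------------------------------------------------------------------------
# Canny boundaries


def test_canny_uniform_image_gives_empty_mask(extraction_cfg):
    img = np.full((32, 32), 90, dtype=np.uint8)
    assert not canny_boundaries(img, extraction_cfg).any()


def test_canny_disc_boundary_hugs_the_circle(extraction_cfg):
    img = np.full((64, 64), 20, dtype=np.uint8)
    yy, xx = np.mgrid[:64, :64]
    r = np.hypot(yy - 32, xx - 32)
    img[r <= 12] = 220
    edges = canny_boundaries(img, extraction_cfg)
    assert edges.sum() > 30
    dist = np.abs(r[edges] - 12)
    assert dist.max() <= 2.0


def test_canny_vertical_step_gives_single_line(extraction_cfg):
    img = np.zeros((32, 32), dtype=np.uint8)
    img[:, 16:] = 200
    edges = canny_boundaries(img, extraction_cfg)
    cols = np.unique(np.nonzero(edges)[1])
    assert len(cols) <= 2 and np.all(np.abs(cols - 15.5) <= 2)


# ---------------------------------------------------------------------------
# GrassFire labeling


def _partitions_equal(la, lb):
    if not np.array_equal(la > 0, lb > 0):
        return False
    pairs = set(zip(la[la > 0].ravel(), lb[lb > 0].ravel()))
    a_to_b = {}
    b_to_a = {}
    for a, b in pairs:
        if a_to_b.setdefault(a, b) != b or b_to_a.setdefault(b, a) != a:
            return False
    return True


def test_grassfire_empty_mask():
    labels = grassfire_label(np.zeros((10, 10), dtype=bool))
    assert labels.max() == 0


def test_grassfire_diagonal_connectivity():
    mask = np.zeros((8, 8), dtype=bool)
    mask[3, 3] = mask[4, 4] = True
    assert grassfire_label(mask, connectivity=8).max() == 1
    assert grassfire_label(mask, connectivity=4).max() == 2


def test_grassfire_labels_are_dense_and_raster_ordered(rng):
    mask = rng.random((24, 24)) < 0.4
    labels = grassfire_label(mask, connectivity=8)
    n = labels.max()
    present = np.unique(labels[labels > 0])
    np.testing.assert_array_equal(present, np.arange(1, n + 1))
    # first raster encounter of label k precedes that of label k+1
    firsts = [np.argmax((labels == k).ravel()) for k in range(1, n + 1)]
    assert firsts == sorted(firsts)


@pytest.mark.parametrize("connectivity", [4, 8])
def test_grassfire_agrees_with_flood_fill_oracle(rng, connectivity):
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    for _ in range(30):
        mask = rng.random((32, 32)) < rng.uniform(0.2, 0.7)
        ours = grassfire_label(mask, connectivity)
        oracle, _ = ndimage.label(mask, structure=structure)
        assert _partitions_equal(ours, oracle)


# ---------------------------------------------------------------------------
# object selection


def _labels_from_masks(*masks):
    labels = np.zeros(masks[0].shape, dtype=np.int32)
    for i, m in enumerate(masks, start=1):
        labels[m] = i
    return labels


def test_select_prefers_dense_blob_over_scribble():
    cfg = ExtractionConfig(min_area=20, min_density=0.05)
    blob = np.zeros((64, 64), dtype=bool)
    blob[10:20, 10:18] = True  # density 1.0
    scribble = np.zeros((64, 64), dtype=bool)
    scribble[40, 10:50] = True
    scribble[40:55, 10] = True  # thin L, low density
    chosen = select_tumor_object(_labels_from_masks(blob, scribble), cfg)
    assert np.array_equal(chosen, blob)


def test_select_excludes_border_touching_objects():
    cfg = ExtractionConfig(min_area=10, min_density=0.1)
    edge_obj = np.zeros((32, 32), dtype=bool)
    edge_obj[0:8, 0:8] = True
    chosen = select_tumor_object(_labels_from_masks(edge_obj), cfg)
    assert not chosen.any()  # no tumor found


def test_select_tie_breaks_on_area():
    cfg = ExtractionConfig(min_area=10, min_density=0.1)
    small = np.zeros((64, 64), dtype=bool)
    small[10:15, 10:20] = True  # 50 px, density 1
    large = np.zeros((64, 64), dtype=bool)
    large[30:40, 30:42] = True  # 120 px, density 1
    chosen = select_tumor_object(_labels_from_masks(small, large), cfg)
    assert np.array_equal(chosen, large)


def test_select_fills_ring_interior():
    cfg = ExtractionConfig(min_area=10, min_density=0.1)
    ring = np.zeros((40, 40), dtype=bool)
    yy, xx = np.mgrid[:40, :40]
    r = np.hypot(yy - 20, xx - 20)
    ring[(r >= 8) & (r <= 10)] = True
    chosen = select_tumor_object(_labels_from_masks(ring), cfg)
    assert chosen[20, 20]  # interior filled
    assert chosen.sum() > ring.sum()


def test_object_stats_geometry():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:10, 8:12] = True
    (st,) = object_stats(_labels_from_masks(mask))
    assert st.area == 20
    assert st.bbox == (5, 8, 10, 12)
    assert st.density == 1.0
    assert st.centroid == (7.0, 9.5)


# ---------------------------------------------------------------------------
# full chain


def test_extract_gist_recovers_phantom_lesion(gist_phantom, extraction_cfg):
    _, img, truth = gist_phantom
    mask = extract_gist(img, extraction_cfg)
    assert iou(mask, truth) >= 0.5


def test_extract_gist_recovers_cyst_lesion(cyst_phantom, extraction_cfg):
    _, img, truth = cyst_phantom
    mask = extract_gist(img, extraction_cfg)
    assert iou(mask, truth) >= 0.5


def test_extract_gist_blank_image_finds_nothing(extraction_cfg):
    img = np.full((64, 64), 128, dtype=np.uint8)
    assert not extract_gist(img, extraction_cfg).any()


def test_extract_gist_is_deterministic(gist_phantom, extraction_cfg):
    _, img, _ = gist_phantom
    np.testing.assert_array_equal(
        extract_gist(img, extraction_cfg), extract_gist(img, extraction_cfg)
    )


def test_extract_gist_stable_under_background_padding(gist_phantom, extraction_cfg):
    _, img, _ = gist_phantom
    pad = 16
    padded = np.pad(img, pad, constant_values=0)
    base = extract_gist(img, extraction_cfg)
    shifted = extract_gist(padded, extraction_cfg)[pad:-pad, pad:-pad]
    # frequency-domain smoothing makes padding only approximately neutral
    assert iou(base, shifted) >= 0.95
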