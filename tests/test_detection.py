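"""Background estimation, masks, components, merging and the size rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrequant import (
    CalibratedImage,
    PipelineConfig,
    TissueLabelMap,
    assign_tissue,
    detect_fibres,
    estimate_background,
    extract_components,
    make_mask,
    merge_components,
    size_filter,
)
from fibrequant._geometry import capsule_pixels
from fibrequant.detection import background_stats

# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def test_constant_raster_has_zero_sd():
    mu, sd = estimate_background(np.full((20, 20), 7.5))
    assert (mu, sd) == (7.5, 0.0)


def test_population_sd_convention():
    """Two-level raster {0, 10} in equal parts: mean 5, population SD 5."""
    raster = np.array([[0.0, 0.0, 10.0, 10.0]]).repeat(50, axis=0)
    mu, sd = estimate_background(raster)
    assert (mu, sd) == (5.0, 5.0)


def test_background_recovery_with_fibres_excluded(rng):
    bg = rng.normal(100, 10, (200, 200))
    img = bg.copy()
    bright = np.zeros_like(img, dtype=bool)
    bright[50:60, :] = True
    img[bright] += 70
    mu, sd = estimate_background(img, exclusion_mask=bright)
    assert abs(mu - 100) < 1.0
    assert abs(sd - 10) < 0.5


def test_too_few_pixels_rejected():
    with pytest.raises(ValueError):
        estimate_background(np.ones((5, 5)))
    with pytest.raises(ValueError):
        estimate_background(np.ones((20, 20)), exclusion_mask=np.ones((20, 20), bool))


def test_iterative_mode_resists_bright_structures(rng):
    img = rng.normal(100, 10, (300, 300))
    img[:30, :] += 100  # 10% of pixels very bright
    mu_naive, sd_naive = background_stats(img, mode="naive")
    mu_iter, sd_iter = background_stats(img, mode="iterative")
    assert sd_naive > 20  # inflated
    assert abs(mu_iter - 100) < 3
    assert sd_iter < sd_naive


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def test_constant_image_yields_empty_mask():
    raster = np.full((50, 50), 3.0)
    mu, sd = 3.0, 0.0
    assert not make_mask(raster, mu, sd).mask.any()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.floats(0.1, 10.0),
    b=st.floats(-50.0, 50.0),
    seed=st.integers(0, 10_000),
)
def test_mask_invariant_under_affine_intensity_transform(a, b, seed):
    """Positive affine rescaling with re-estimated background: same mask."""
    r = np.random.default_rng(seed)
    img = r.normal(100, 10, (60, 60))
    img[20:30, 20:40] += 80
    for mode in ("naive", "iterative"):
        m1 = make_mask(img, *background_stats(img, mode))
        img2 = a * img + b
        m2 = make_mask(img2, *background_stats(img2, mode))
        assert np.array_equal(m1.mask, m2.mask)


def test_false_positive_fraction_matches_gaussian_tail(rng):
    """At the true background parameters ~2.28% of noise pixels exceed +2SD."""
    img = rng.normal(50, 5, (400, 400))
    frac = make_mask(img, 50, 5).mask.mean()
    assert abs(frac - 0.0228) < 0.002


def test_mask_pixels_strictly_exceed_threshold(rng):
    img = rng.normal(0, 1, (100, 100))
    m = make_mask(img, 0.0, 1.0)
    assert (img[m.mask] > m.threshold_value).all()
    assert (img[~m.mask] <= m.threshold_value).all()


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


def flood_fill_oracle(mask):
    """Brute-force 8-connected labelling by stack-based flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0]
                                    and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(frozenset(comp))
    return set(comps)


def test_empty_mask_gives_no_components():
    assert extract_components(np.zeros((10, 10), bool)) == []


def test_diagonal_pixels_are_one_component():
    m = np.zeros((5, 5), bool)
    m[1, 1] = m[2, 2] = True
    assert len(extract_components(m)) == 1


@pytest.mark.parametrize("seed", range(10))
def test_components_match_flood_fill_oracle(seed):
    r = np.random.default_rng(seed)
    mask = r.random((20, 20)) < 0.3
    got = {
        frozenset(map(tuple, c.tolist())) for c in extract_components(mask)
    }
    assert got == flood_fill_oracle(mask)


# ---------------------------------------------------------------------------
# tissue assignment
# ---------------------------------------------------------------------------


def _labelmap(arr):
    return TissueLabelMap(np.asarray(arr, np.uint8), pixel_size_um=0.5)


def test_assign_tissue_majority_and_ties():
    labels = np.zeros((10, 10), np.uint8)
    labels[:, :5] = 1  # myocyte left, none right
    lm = _labelmap(labels)
    inside_myo = np.array([[2, 2], [3, 3], [4, 4]])
    assert assign_tissue(inside_myo, lm) == "myocyte"

    labels2 = np.ones((10, 10), np.uint8)
    labels2[:, 5:] = 2
    lm2 = _labelmap(labels2)
    # 3 myocyte vs 2 connective pixels -> myocyte
    fp = np.array([[0, 3], [0, 4], [1, 4], [0, 5], [0, 6]])
    assert assign_tissue(fp, lm2) == "myocyte"
    # exact tie -> connective
    fp_tie = np.array([[0, 4], [0, 5]])
    assert assign_tissue(fp_tie, lm2) == "connective"
    # all pixels unlabelled -> connective
    assert assign_tissue(np.array([[0, 0]]), _labelmap(np.zeros((5, 5)))) == "connective"


def test_assign_tissue_rejects_out_of_bounds():
    with pytest.raises(ValueError):
        assign_tissue(np.array([[99, 0]]), _labelmap(np.zeros((5, 5))))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _bar(r0, c0, length=12, width=3):
    rr, cc = np.meshgrid(np.arange(width), np.arange(length), indexing="ij")
    return np.stack([(rr + r0).ravel(), (cc + c0).ravel()], 1).astype(np.intp)


def test_components_beyond_merge_distance_stay_apart():
    # collinear bars, gap 12 px = 6 um at 0.5 um/px
    comps = [(_bar(0, 0), "connective"), (_bar(0, 24), "connective")]
    assert len(merge_components(comps, pixel_size_um=0.5)) == 2


def test_close_components_in_different_tissues_stay_apart():
    comps = [(_bar(0, 0), "connective"), (_bar(0, 18), "myocyte")]
    assert len(merge_components(comps, pixel_size_um=0.5)) == 2


def test_collinear_close_components_merge():
    comps = [(_bar(0, 0), "connective"), (_bar(0, 18), "connective")]  # 3 um gap
    merged = merge_components(comps, pixel_size_um=0.5)
    assert len(merged) == 1
    assert len(merged[0][0]) == 72


def test_orientation_gate_blocks_perpendicular_components():
    horiz = _bar(0, 0, length=20, width=3)
    vert = np.stack([np.arange(6, 26), np.full(20, 25)], 1)
    vert = np.concatenate([vert, vert + [0, 1], vert + [0, 2]])
    comps = [(horiz, "connective"), (vert.astype(np.intp), "connective")]
    assert len(merge_components(comps, pixel_size_um=0.5)) == 2
    # disabling the gate makes the rule purely distance-based
    assert len(merge_components(comps, pixel_size_um=0.5,
                                orientation_gate_deg=None)) == 1


def test_small_components_never_merge_by_default():
    speck = np.array([[1, 18]], dtype=np.intp)  # 3.5 um from the bar
    comps = [(_bar(0, 0), "connective"), (speck, "connective")]
    assert len(merge_components(comps, pixel_size_um=0.5)) == 2
    assert len(merge_components(comps, pixel_size_um=0.5,
                                small_component_policy="merge")) == 1


def test_merge_is_idempotent(rng):
    from .conftest import random_footprint

    comps = []
    for k in range(12):
        fp = random_footprint(rng, n_min=12, n_max=40, span=12)
        fp = fp + rng.integers(0, 80, size=2)
        comps.append((fp, "connective" if k % 2 else "myocyte"))
    once = merge_components(comps, pixel_size_um=0.5)
    twice = merge_components(once, pixel_size_um=0.5)
    as_sets = lambda cs: {frozenset(map(tuple, c.tolist())) for c, _ in cs}
    assert as_sets(once) == as_sets(twice)


# ---------------------------------------------------------------------------
# size filter
# ---------------------------------------------------------------------------


def test_size_filter_examples():
    px = 0.5
    single = (np.array([[5, 5]], dtype=np.intp), "connective")
    rr, cc = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
    square = (np.stack([rr.ravel(), cc.ravel()], 1), "connective")  # 5x5 um
    rr, cc = np.meshgrid(np.arange(2), np.arange(20), indexing="ij")
    thin_bar = (np.stack([rr.ravel(), cc.ravel()], 1), "myocyte")  # 10x1 um

    fibres = size_filter([single, square, thin_bar], px)
    assert len(fibres) == 1
    assert fibres[0].tissue == "connective"
    assert fibres[0].width_um == pytest.approx(5.0)
    assert fibres[0].length_um >= fibres[0].width_um >= 4.0


# ---------------------------------------------------------------------------
# full detection chain
# ---------------------------------------------------------------------------


def _image_with(footprints, shape=(128, 128), amp=10.0, seed=0):
    rng = np.random.default_rng(seed)
    raster = rng.normal(100, 1.0, shape)
    for fp in footprints:
        raster[fp[:, 0], fp[:, 1]] += amp
    channels = {ch: raster.copy() for ch in ("PGP95", "SP", "NR2B", "NGF")}
    return CalibratedImage(channels, pixel_size_um=0.5, image_id="t")


def test_fragments_with_small_gap_detected_as_one_fibre():
    cap = capsule_pixels((64, 64), 0.3, 40, 12, (128, 128))
    proj = (cap - np.array([64.0, 64.0])) @ np.array([np.cos(0.3), np.sin(0.3)])
    frag = cap[np.abs(proj) > 4.0]  # 4 px = 2 um gap in the middle
    img = _image_with([frag])
    labels = TissueLabelMap(np.full((128, 128), 2, np.uint8), 0.5)
    fs = detect_fibres(img, labels)
    assert len(fs) == 1
    assert fs.fibres[0].tissue == "connective"


def test_fragments_beyond_merge_distance_stay_two_fibres():
    a = capsule_pixels((40, 40), 0.0, 24, 12, (128, 128))
    b = capsule_pixels((40, 76), 0.0, 24, 12, (128, 128))  # ~12 px = 6 um gap
    img = _image_with([a, b])
    labels = TissueLabelMap(np.full((128, 128), 2, np.uint8), 0.5)
    assert len(detect_fibres(img, labels)) == 2


def test_small_speck_filtered_out():
    speck = capsule_pixels((30, 30), 0.0, 6, 6, (128, 128))  # 3 um x 3 um
    fibre = capsule_pixels((80, 80), 0.5, 30, 12, (128, 128))
    img = _image_with([speck, fibre])
    labels = TissueLabelMap(np.full((128, 128), 1, np.uint8), 0.5)
    fs = detect_fibres(img, labels)
    assert len(fs) == 1
    assert fs.fibres[0].tissue == "myocyte"


def test_every_detected_fibre_satisfies_type_invariants(tiny_dataset):
    cfg = PipelineConfig()
    for image, labelmap in zip(tiny_dataset.images[:4], tiny_dataset.labelmaps[:4]):
        fs = detect_fibres(image, labelmap, cfg)
        assert fs.counts["myocyte"] + fs.counts["connective"] == len(fs)
        for f in fs.fibres:
            assert f.length_um >= f.width_um >= 4.0
            assert f.tissue in ("myocyte", "connective")
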