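"""Microscopy quantification: segmentation ops, propagation oracle, assays."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import disk

from episcreen import synthetic
from episcreen.imaging import (
    QuantConfig,
    area_fraction,
    combine_replicates,
    detect_nuclei,
    normalize_intensity,
    propagate_cytoplasm,
    quantify_cells,
    quantify_scene,
    segment_droplets,
    sigmoid_transform,
    summarize_condition,
    threshold_mask,
    tophat,
)


def _disk_image(shape, centers_radii, level, background=0.0):
    img = np.full(shape, background)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for (r0, c0, rad) in centers_radii:
        d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
        img += (level - background) * np.clip(rad + 0.5 - d, 0, 1)
    return img


# --- intensity ops ----------------------------------------------------------


def test_normalize_affine_invariance(rng):
    img = rng.uniform(size=(30, 30))
    np.testing.assert_allclose(
        normalize_intensity(img), normalize_intensity(3.0 * img + 7.0), atol=1e-12
    )


def test_normalize_ramp_percentile_endpoints():
    ramp = np.tile(np.linspace(0, 1, 100), (100, 1))
    out = normalize_intensity(ramp)
    lo, hi = np.percentile(ramp, (1, 99))
    assert out[0, ramp[0] <= lo].max() == 0.0
    assert out[0, ramp[0] >= hi].min() == 1.0


def test_normalize_constant_errors():
    with pytest.raises(ValueError):
        normalize_intensity(np.full((10, 10), 0.5))


def test_sigmoid_midpoint_and_monotonicity(rng):
    assert sigmoid_transform(np.array([0.3]), 0.3, 10.0)[0] == pytest.approx(0.5)
    x = np.sort(rng.uniform(size=50))
    s = sigmoid_transform(x, 0.5, 7.0)
    assert (np.diff(s) >= 0).all()
    with pytest.raises(ValueError):
        sigmoid_transform(x, 0.5, 0.0)


def test_threshold_fixed_and_otsu_bimodal():
    img = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 0.1, 0.9)
    assert np.array_equal(threshold_mask(img, 0.5), img >= 0.5)
    assert np.array_equal(threshold_mask(img, "otsu"), img >= 0.5)


def _between_class_variances(img, nbins=256):
    """Exhaustive 256-threshold search objective, one value per split."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    vs = np.full(nbins - 1, -np.inf)
    for i in range(1, nbins):
        w0, w1 = counts[:i].sum(), counts[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:i] * centers[:i]).sum() / w0
        m1 = (counts[i:] * centers[i:]).sum() / w1
        vs[i - 1] = w0 * w1 * (m0 - m1) ** 2
    return centers, vs


def test_otsu_achieves_exhaustive_search_maximum(rng):
    # the objective can plateau (ties across near-empty bins), so assert the
    # chosen threshold attains the brute-force maximum rather than comparing
    # the tie-broken threshold values themselves
    img = np.r_[rng.normal(0.2, 0.05, 600), rng.normal(0.8, 0.05, 400)].reshape(-1, 10)
    from skimage.filters import threshold_otsu

    t = threshold_otsu(img, nbins=256)
    centers, vs = _between_class_variances(img)
    split = int(np.argmin(np.abs(centers[:-1] - t)))
    assert vs[split] == pytest.approx(vs.max(), rel=1e-9)


# --- top-hat ----------------------------------------------------------------


def test_tophat_flat_image_is_zero():
    np.testing.assert_allclose(tophat(np.full((20, 20), 0.4), 5), 0.0)


def test_tophat_keeps_small_removes_large():
    small = _disk_image((40, 40), [(20, 20, 2)], 1.0)
    th_small = tophat(small, 5)
    assert th_small[20, 20] == pytest.approx(1.0)
    large = _disk_image((60, 60), [(30, 30, 20)], 1.0)
    th_large = tophat(large, 5)
    assert th_large[30, 30] == pytest.approx(0.0, abs=1e-9)
    assert (th_large >= -1e-12).all() and (th_large <= large + 1e-12).all()


# --- nuclei -----------------------------------------------------------------


def test_detect_nuclei_blank_gives_empty_mask():
    assert detect_nuclei(np.zeros((64, 64))).max() == 0


def test_detect_nuclei_five_separated():
    centers = [(20, 20), (20, 70), (70, 20), (70, 70), (45, 45)]
    img = _disk_image((96, 96), [(r, c, 10) for r, c in centers], 0.9, 0.05)
    labels = detect_nuclei(img)
    assert labels.max() == 5
    # each detected centroid within 2 px of a true center
    from skimage.measure import regionprops

    found = [p.centroid for p in regionprops(labels)]
    for r0, c0 in centers:
        assert min((fr - r0) ** 2 + (fc - c0) ** 2 for fr, fc in found) <= 4.0


def test_detect_nuclei_splits_touching_pair():
    img = _disk_image((60, 90), [(30, 30, 12), (30, 48, 12)], 0.9, 0.05)
    labels = detect_nuclei(img, min_distance=10)
    assert labels.max() == 2


# --- propagation ------------------------------------------------------------


def _dijkstra_nearest_seed(seeds, mask):
    """Independent oracle: per-seed geodesic distance via scipy dijkstra."""
    H, W = mask.shape
    idx = -np.ones((H, W), dtype=int)
    coords = np.argwhere(mask)
    for i, (r, c) in enumerate(coords):
        idx[r, c] = i
    n = len(coords)
    g = lil_matrix((n, n))
    moves = [(-1, -1, np.sqrt(2)), (-1, 0, 1.0), (-1, 1, np.sqrt(2)), (0, 1, 1.0)]
    for i, (r, c) in enumerate(coords):
        for dr, dc, w in moves:
            nr, nc = r + dr, c + dc
            if 0 <= nr < H and 0 <= nc < W and mask[nr, nc]:
                j = idx[nr, nc]
                g[i, j] = w
                g[j, i] = w
    labels = sorted(set(seeds[seeds > 0]))
    dists = np.full((len(labels), n), np.inf)
    for li, lab in enumerate(labels):
        sources = [idx[r, c] for r, c in np.argwhere((seeds == lab) & mask)]
        d = dijkstra(g.tocsr(), indices=sources, directed=False)
        dists[li] = d.min(axis=0) if d.ndim == 2 else d
    return coords, np.array(labels), dists


def test_propagation_uniform_intensity_is_nearest_seed():
    rng = np.random.default_rng(3)
    mask = np.ones((32, 32), dtype=bool)
    mask[10:22, 15:17] = False  # a wall, so geodesic != straight-line
    seeds = np.zeros((32, 32), dtype=int)
    seeds[4, 4] = 1
    seeds[28, 28] = 2
    img = np.full((32, 32), 0.5)
    out = propagate_cytoplasm(seeds, img, mask, lam=1.0)
    coords, labels, dists = _dijkstra_nearest_seed(seeds, mask)
    for (r, c), dcol in zip(coords, dists.T):
        got = out[r, c]
        best = dcol.min()
        assert np.isfinite(best)
        # assigned seed must achieve the minimal geodesic distance
        assert dcol[list(labels).index(got)] == pytest.approx(best, abs=1e-9)


def test_propagation_respects_mask_and_errors():
    seeds = np.zeros((16, 16), dtype=int)
    seeds[2, 2] = 1
    img = np.full((16, 16), 0.5)
    mask = np.ones((16, 16), dtype=bool)
    mask[:, 10:] = False
    out = propagate_cytoplasm(seeds, img, mask)
    assert (out[:, 10:] == 0).all()
    assert (out[:, :10] == 1).all()
    with pytest.raises(ValueError):
        propagate_cytoplasm(np.zeros((16, 16), int), img, mask)


def test_propagation_clips_outside_seeds_with_warning():
    seeds = np.zeros((16, 16), dtype=int)
    seeds[2, 2] = 1
    seeds[2, 14] = 2  # outside the mask
    img = np.full((16, 16), 0.5)
    mask = np.ones((16, 16), dtype=bool)
    mask[:, 10:] = False
    with pytest.warns(UserWarning):
        out = propagate_cytoplasm(seeds, img, mask)
    assert set(np.unique(out)) == {0, 1}


def test_propagation_boundary_follows_bright_ridge():
    """With a strong intensity ridge the cheap path avoids crossing it."""
    H, W = 32, 32
    img = np.zeros((H, W))
    img[:, 15] = 1.0  # bright vertical ridge
    mask = np.ones((H, W), dtype=bool)
    seeds = np.zeros((H, W), dtype=int)
    seeds[16, 2] = 1
    seeds[16, 29] = 2
    out = propagate_cytoplasm(seeds, img, mask, lam=1e-4)
    # left of ridge belongs to seed 1, right to seed 2
    assert (out[:, :15] == 1).all()
    assert (out[:, 16:] == 2).all()


# --- droplets and quantification -------------------------------------------


def test_segment_droplets_blank_is_empty():
    cells = np.ones((40, 40), dtype=int)
    assert segment_droplets(np.zeros((40, 40)), cells).max() == 0


def test_segment_droplets_counts_planted_dots():
    cells = np.ones((100, 100), dtype=int)
    pts = [(r, c, 2.0) for r in (20, 50, 80) for c in (20, 50, 80)]
    img = _disk_image((100, 100), pts, 0.9, 0.1)
    dots = segment_droplets(img, cells)
    assert dots.max() == 9


def test_segment_droplets_min_area_filter():
    cells = np.ones((40, 40), dtype=int)
    img = np.full((40, 40), 0.1)
    img[10, 10] = 0.9  # area-1 dot
    img[25:28, 25:28] = 0.9  # area-9 dot
    dots = segment_droplets(img, cells, min_dot_area=2)
    assert dots.max() == 1
    assert dots[10, 10] == 0


def test_segment_droplets_outside_cells_discarded():
    cells = np.zeros((60, 60), dtype=int)
    cells[0:30, :] = 1
    img = _disk_image((60, 60), [(15, 30, 2), (45, 30, 2)], 0.9, 0.1)
    dots = segment_droplets(img, cells)
    assert dots.max() == 1


def test_quantify_cells_arithmetic():
    cells = np.zeros((40, 50), dtype=int)
    cells[:20, :50] = 1  # area 1000
    dots = np.zeros_like(cells)
    dots[2:4, 2:7] = 1  # 10 px
    dots[6:8, 2:7] = 2
    dots[10:12, 2:7] = 3
    q = quantify_cells(cells, dots)
    row = q.set_index("cell").loc[1]
    assert row["n_dots"] == 3
    assert row["count_per_area"] == pytest.approx(0.003)
    assert row["area_fraction"] == pytest.approx(0.03)


def test_quantify_cells_no_dots_zeros():
    cells = np.ones((10, 10), dtype=int)
    q = quantify_cells(cells, np.zeros((10, 10), dtype=int))
    assert q.loc[0, "n_dots"] == 0 and q.loc[0, "area_fraction"] == 0


def test_full_scene_recovers_truth_and_is_deterministic():
    spec = synthetic.ImageSceneSpec(seed=5)
    img, truth = synthetic.gen_fluor_scene(spec)
    cells, dots, q = quantify_scene(img[0], img[1])
    assert cells.max() == len(truth.nuclei)
    assert dots.max() == truth.n_droplets
    assert sorted(q["n_dots"]) == sorted(len(v) for v in truth.droplets.values())
    again = quantify_scene(img[0], img[1])[2]
    pd.testing.assert_frame_equal(q, again)


def test_summarize_condition_fold_change():
    cells = pd.DataFrame(
        {
            "condition": ["control"] * 4 + ["treated"] * 4,
            "view_field": [1, 1, 2, 2, 1, 1, 2, 2],
            "count_per_area": [2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0],
            "area_fraction": [0.2] * 4 + [0.1] * 4,
        }
    )
    out = summarize_condition(cells).set_index("condition")
    assert out.loc["control", "count_per_area_fc"] == pytest.approx(1.0)
    assert out.loc["treated", "count_per_area_fc"] == pytest.approx(0.5)


def test_summarize_condition_matches_two_level_average(rng):
    rows = []
    for cond in ("control", "kd"):
        for fieldid in range(3):
            for _ in range(int(rng.integers(2, 6))):
                rows.append(
                    {
                        "condition": cond,
                        "view_field": fieldid,
                        "count_per_area": rng.uniform(0.5, 2),
                        "area_fraction": rng.uniform(0.01, 0.2),
                    }
                )
    cells = pd.DataFrame(rows)
    out = summarize_condition(cells).set_index("condition")
    for cond in ("control", "kd"):
        sub = cells[cells["condition"] == cond]
        field_means = [
            sub[sub["view_field"] == f]["count_per_area"].mean()
            for f in sorted(sub["view_field"].unique())
        ]
        assert out.loc[cond, "count_per_area_mean"] == pytest.approx(
            np.mean(field_means)
        )


def test_area_fraction_trivial_extremes():
    assert area_fraction(np.full((20, 20), 0.95), invert=True) == 0.0
    assert area_fraction(np.full((20, 20), 0.02), invert=True) == 1.0
    assert area_fraction(np.zeros((20, 20))) == 0.0


def test_area_fraction_recovers_planted_fraction():
    for target in (0.3, 0.5, 0.7):
        img, truth = synthetic.gen_stained_image(
            target, synthetic.StainSpec(seed=9, gaussian_noise_sd=0.02)
        )
        est = area_fraction(img, invert=True)
        assert abs(est - truth.covered_fraction) <= 0.02


def test_combine_replicates_two_level_mean():
    tab = pd.DataFrame(
        {
            "condition": ["a", "a", "a", "b"],
            "replicate": [1, 1, 2, 1],
            "fraction": [0.2, 0.4, 0.6, 0.5],
        }
    )
    out = combine_replicates(tab)
    assert out["a"] == pytest.approx((0.3 + 0.6) / 2)
    assert out["b"] == pytest.approx(0.5)
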