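"""Segmentation, the G-function, envelope simulation, and classification."""

import numpy as np
import pytest

from thymod import (
    analyse_pattern,
    classify_pattern,
    default_r_grid,
    g_function,
    generate_image,
    nearest_neighbour_distances,
    sample_points,
    segment_medulla,
    segment_positive_cells,
    simulate_reference,
)
from thymod.simulate import _render_spots
from thymod.spatial import GFunctionResult, merge_unresolved


@pytest.fixture(scope="module")
def disc_mask():
    yy, xx = np.mgrid[0:200, 0:200]
    return (xx - 100) ** 2 + (yy - 100) ** 2 < 90 ** 2


# ---------------------------------------------------------------------------
# Point samplers
# ---------------------------------------------------------------------------

def test_samplers_stay_inside_mask(disc_mask, rng):
    for kind in ("even", "random", "clustered"):
        pts = sample_points(disc_mask, 40, kind, rng)
        xi = np.round(pts[:, 0]).astype(int)
        yi = np.round(pts[:, 1]).astype(int)
        assert disc_mask[yi, xi].all()


def test_even_sampler_enforces_radius(disc_mask, rng):
    pts = sample_points(disc_mask, 30, "even", rng, inhibition_radius=15.0)
    assert nearest_neighbour_distances(pts).min() >= 15.0


def test_infeasible_inhibition_packing_raises(disc_mask, rng):
    with pytest.raises(ValueError, match="inhibition"):
        sample_points(disc_mask, 100, "even", rng, inhibition_radius=100.0,
                      max_attempts_factor=10)


def test_empty_mask_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        sample_points(np.zeros((10, 10), bool), 3, "random", rng)


def test_unknown_kind_rejected(disc_mask, rng):
    with pytest.raises(ValueError, match="kind"):
        sample_points(disc_mask, 3, "spiral", rng)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def test_constant_image_yields_error():
    with pytest.raises(ValueError, match="mask"):
        segment_medulla(np.zeros((64, 64)))


def test_single_blob_mask_area_recovered():
    img, truth = generate_image(kind="random", n_points=5, noise_sd=0.0, seed=9)
    mask = segment_medulla(img[0], sigma=4)
    true_area = truth.mask.sum()
    assert abs(mask.sum() - true_area) / true_area < 0.10


def test_mask_stable_under_small_noise(rng):
    img, _ = generate_image(kind="random", n_points=5, noise_sd=0.0, seed=9)
    clean = segment_medulla(img[0], sigma=4, threshold=0.5)
    noisy_channel = img[0] + rng.normal(0, 0.01 * img[0].max(), img[0].shape)
    noisy = segment_medulla(noisy_channel, sigma=4, threshold=0.5)
    differing = np.logical_xor(clean, noisy).sum()
    assert differing <= 0.002 * clean.sum()


def test_planted_spots_recovered_within_two_pixels():
    img, truth = generate_image(kind="even", n_points=25, noise_sd=0.0, seed=5)
    seg = segment_positive_cells(img[1], sigma=2)
    assert len(seg.centroids) == 25
    from scipy.spatial import cKDTree

    d, _ = cKDTree(truth.true_centroids).query(seg.centroids)
    assert d.max() < 2.0


def test_touching_spots_split_by_watershed():
    img = np.zeros((100, 100))
    pts = np.array([[40.0, 50.0], [49.0, 50.0]])  # 1.5x spot radius apart
    img = _render_spots(img.shape, pts, 3.0)
    seg = segment_positive_cells(img, sigma=1.0, min_peak_distance=2)
    assert len(seg.centroids) == 2


def test_empty_channel_gives_valid_empty_result():
    seg = segment_positive_cells(np.zeros((50, 50)))
    assert len(seg.centroids) == 0
    assert seg.labels.max() == 0


def test_centroids_outside_mask_dropped():
    img = _render_spots((80, 80), np.array([[10.0, 10.0], [70.0, 70.0]]), 2.0)
    mask = np.zeros((80, 80), bool)
    mask[:40, :40] = True
    seg = segment_positive_cells(img, sigma=1.0, mask=mask)
    assert len(seg.centroids) == 1
    assert tuple(np.round(seg.centroids[0])) == (10, 10)


# ---------------------------------------------------------------------------
# G-function
# ---------------------------------------------------------------------------

def test_two_points_give_step_function():
    pts = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
    rg = np.array([4.0, 5.0, 6.0])
    g = g_function(pts, rg).g_observed
    assert list(g) == [0.0, 1.0, 1.0]


def test_regular_grid_jumps_at_spacing():
    xx, yy = np.meshgrid(np.arange(0, 100, 10.0), np.arange(0, 100, 10.0))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    rg = np.array([9.9, 10.0])
    g = g_function(pts, rg).g_observed
    assert list(g) == [0.0, 1.0]


def test_poisson_pattern_matches_closed_form(rng):
    pts = rng.uniform(0, 1000, size=(2000, 2))
    lam = 2000 / 1000 ** 2
    rg = np.linspace(0, 0.5 / np.sqrt(lam), 40)
    g = g_function(pts, rg).g_observed
    theo = 1 - np.exp(-lam * np.pi * rg ** 2)
    assert np.abs(g - theo).max() <= 0.05


def test_g_invariant_to_ordering_and_rotation(rng):
    pts = rng.uniform(20, 80, size=(60, 2))
    rg = np.linspace(0, 30, 25)
    base = g_function(pts, rg).g_observed
    shuffled = g_function(pts[rng.permutation(60)], rg).g_observed
    rotated = g_function(np.column_stack([pts[:, 1], 100 - pts[:, 0]]), rg).g_observed
    np.testing.assert_allclose(base, shuffled)
    np.testing.assert_allclose(base, rotated)


def test_fewer_than_two_points_rejected():
    with pytest.raises(ValueError):
        g_function(np.array([[1.0, 1.0]]), np.array([1.0]))


def test_merge_unresolved_collapses_close_pairs():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]])
    merged = merge_unresolved(pts, 2.0)
    assert len(merged) == 2
    assert ([0.5, 0.0] == merged).all(axis=1).any()


# ---------------------------------------------------------------------------
# Envelopes and classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def reference_envelopes(disc_mask):
    rg = default_r_grid(disc_mask, 40)
    env = simulate_reference(disc_mask, 40, rg, n_sim=99, seed=0)
    return rg, env


def test_random_envelope_contains_poisson_theory(disc_mask, reference_envelopes):
    rg, env = reference_envelopes
    lam = 40 / disc_mask.sum()
    theo = 1 - np.exp(-lam * np.pi * rg ** 2)
    lo, hi = env["random"].lo, env["random"].hi
    inside = (theo >= lo - 1e-9) & (theo <= hi + 1e-9)
    assert inside.mean() >= 0.95


def test_clustered_band_above_and_even_below_random(reference_envelopes):
    rg, env = reference_envelopes
    small_r = rg < np.median(rg)
    mid = {k: (env[k].lo + env[k].hi) / 2 for k in env}
    assert mid["clustered"][small_r].mean() > mid["random"][small_r].mean()
    assert mid["even"][small_r].mean() < mid["random"][small_r].mean()


def test_classification_requires_all_envelopes(reference_envelopes):
    rg, env = reference_envelopes
    partial = {k: env[k] for k in ("random", "even")}
    res = GFunctionResult(r_grid=rg, g_observed=env["random"].curves[0],
                          envelopes=partial)
    with pytest.raises(ValueError, match="missing envelope"):
        classify_pattern(res)


def test_random_simulations_classified_random(disc_mask, reference_envelopes, rng):
    rg, env = reference_envelopes
    hits = 0
    for i in range(40):
        pts = sample_points(disc_mask, 40, "random", rng)
        res = GFunctionResult(r_grid=rg, g_observed=g_function(pts, rg).g_observed,
                              envelopes=env)
        hits += classify_pattern(res) == "random"
    assert hits >= 36  # alpha = 0.05 rank test: ~95% expected


def test_planted_processes_recovered_from_points(disc_mask, reference_envelopes, rng):
    rg, env = reference_envelopes
    for kind in ("clustered", "even"):
        hits = 0
        for i in range(20):
            pts = sample_points(disc_mask, 40, kind, rng)
            res = GFunctionResult(
                r_grid=rg, g_observed=g_function(pts, rg).g_observed, envelopes=env
            )
            hits += classify_pattern(res) == kind
        assert hits >= 18


def test_end_to_end_image_classification_smoke():
    img, truth = generate_image(kind="clustered", n_points=50, noise_sd=0.01, seed=21)
    mask = segment_medulla(img[0], sigma=4)
    seg = segment_positive_cells(img[1], sigma=2, mask=mask)
    res = analyse_pattern(
        seg.centroids, mask, n_sim=49, seed=1,
        merge_radius=2 * np.hypot(3.0, 2.0),
    )
    assert res.classification == "clustered"
    assert res.p_random is not None and res.p_random < 0.05
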