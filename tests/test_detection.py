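"""Spot / nucleus / dark-region detection against constructed images and
simulator truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from blastula import (SimConfig, NoiseParams, Movie, simulate_truth,
                      render_movie, DetectionParams, max_project,
                      detect_spots, detect_nuclei, detect_dark_regions)
from blastula import benchmark

VOX = (0.5, 0.5, 1.0)


# ---------------------------------------------------------------------------
# max projection
# ---------------------------------------------------------------------------

def test_max_project_identity_for_single_plane(rng):
    data = rng.integers(0, 100, (2, 2, 1, 8, 8)).astype(np.uint16)
    mov = Movie(data, ("h2b", "mo"), VOX, 51.0)
    mip = max_project(mov, "mo")
    assert np.array_equal(mip.data[:, 0], mov.data[:, 1])
    assert mip.voxel_size_um == VOX


def test_max_project_zeros_and_single_voxel():
    data = np.zeros((1, 1, 5, 8, 8), dtype=np.uint16)
    data[0, 0, 3, 4, 5] = 77
    mov = Movie(data, ("mo",), VOX, 51.0)
    mip = max_project(mov, "mo")
    assert mip.data.sum() == 77
    assert mip.data[0, 0, 0, 4, 5] == 77
    with pytest.raises(ValueError, match="unknown channel"):
        max_project(mov, "h2b")


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------

def _blob_frame(shape=(64, 64), centre=(32.3, 40.7), sigma=1.3,
                amp=120.0, noise_sd=3.0, seed=0):
    yy, xx = np.indices(shape).astype(float)
    img = amp * np.exp(-(((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2)
                         / (2 * sigma ** 2)))
    rng = np.random.default_rng(seed)
    return img + 100 + rng.normal(0, noise_sd, shape)


def test_blank_frame_yields_no_spots():
    assert detect_spots(np.full((64, 64), 100.0),
                        DetectionParams.foci_2d()) == []


def test_single_gaussian_blob_recovered_within_one_pixel():
    img = _blob_frame()
    spots = detect_spots(img, DetectionParams.foci_2d(), voxel_size_um=VOX)
    assert len(spots) == 1
    cy, cx = spots[0].centroid_px
    assert abs(cy - 32.3) < 1.0 and abs(cx - 40.7) < 1.0


def test_default_parameters_match_field_conventions():
    p = DetectionParams.foci_2d()
    assert (p.scale_px, p.min_size, p.max_size) == (3, 3, 75)
    assert 80 <= p.sensitivity_pct <= 150
    n = DetectionParams.nuclei_2d()
    assert (n.min_size, n.max_size) == (200, 3000)
    assert (DetectionParams.foci_3d().min_size,
            DetectionParams.foci_3d().max_size) == (5, 150)
    assert (DetectionParams.nuclei_3d().min_size,
            DetectionParams.nuclei_3d().max_size) == (750, 20000)


def test_non_finite_pixels_are_rejected():
    img = np.full((32, 32), 100.0)
    img[3, 3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        detect_spots(img, DetectionParams.foci_2d())


def test_mode_must_match_dimensionality():
    with pytest.raises(ValueError, match="mode"):
        detect_spots(np.zeros((4, 8, 8)), DetectionParams.foci_2d())


def test_sensitivity_is_monotone(default_movie):
    img = default_movie.data[len(default_movie.data) // 2, 1].max(axis=0)
    counts = [len(detect_spots(img.astype(float),
                               DetectionParams.foci_2d(sensitivity_pct=s),
                               voxel_size_um=VOX))
              for s in (50, 80, 100, 120, 150, 200)]
    assert counts == sorted(counts)


def test_size_window_is_enforced_exactly(default_movie):
    img = default_movie.data[len(default_movie.data) // 2, 1].max(axis=0)
    for lo, hi in [(3, 75), (10, 40), (30, 200)]:
        spots = detect_spots(img.astype(float),
                             DetectionParams.foci_2d(min_size=lo, max_size=hi),
                             voxel_size_um=VOX)
        assert all(lo <= s.size <= hi for s in spots)


def test_detection_is_scale_equivariant():
    img = _blob_frame(noise_sd=0.0)
    big = ndi.zoom(img, 2.0, order=1)
    n1 = len(detect_spots(img, DetectionParams.foci_2d(), voxel_size_um=VOX))
    n2 = len(detect_spots(big, DetectionParams.foci_2d(scale_px=6,
                                                       min_size=12,
                                                       max_size=300),
                          voxel_size_um=VOX))
    assert n1 == n2 == 1


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def test_noise_free_frame_recovers_every_nucleus(noisefree_movie,
                                                 noisefree_truth):
    k = noisefree_movie.n_frames // 2
    img = noisefree_movie.data[k, 0].max(axis=0).astype(float)
    obs, labels = detect_nuclei(
        img, DetectionParams.nuclei_2d(min_size=25, max_size=700),
        voxel_size_um=VOX, frame=k)
    alive = noisefree_truth.alive_at(k * 51.0)
    assert len(obs) == len(alive)
    assert labels.max() == len(obs)
    det = np.array([[o.centroid_um[0], o.centroid_um[1]] for o in obs])
    for _, n in alive.iterrows():
        d = np.hypot(det[:, 0] - n.x_um, det[:, 1] - n.y_um).min()
        assert d < 1.2 * n.radius_um


def test_anaphase_pair_is_one_object_with_two_components():
    """Two bright masses closer than a nuclear diameter merge into a single
    detected nucleus whose component_count is 2."""
    img = np.full((96, 96), 100.0)
    yy, xx = np.indices(img.shape).astype(float)
    for cx in (42.0, 54.0):         # 6 um apart at 0.5 um/px
        img += 300.0 * (((yy - 48) ** 2 + (xx - cx) ** 2) <= 16.0)
    img = ndi.gaussian_filter(img, 1.0)
    obs, _ = detect_nuclei(img, DetectionParams.nuclei_2d(min_size=25,
                                                          max_size=700),
                           voxel_size_um=VOX)
    assert len(obs) == 1
    assert obs[0].component_count == 2
    assert obs[0].elongation > 1.5


def test_size_window_outside_all_objects_gives_empty_list(small_movie):
    img = small_movie.data[small_movie.n_frames // 2, 0].max(axis=0)
    obs, labels = detect_nuclei(
        img.astype(float),
        DetectionParams.nuclei_2d(min_size=5000, max_size=20000),
        voxel_size_um=VOX)
    assert obs == [] and labels.max() == 0


def test_foci_precision_and_recall_on_default_movie(default_movie,
                                                    default_truth):
    spots = {}
    for k in range(default_movie.n_frames):
        img = default_movie.data[k, 1].max(axis=0).astype(float)
        spots[k] = detect_spots(img, DetectionParams.foci_2d(),
                                voxel_size_um=VOX, frame=k)
    scores = benchmark.foci_scores(spots, default_truth)
    assert scores["recall"] >= 0.95
    assert scores["precision"] >= 0.95


# ---------------------------------------------------------------------------
# dark regions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def hole_fixture():
    cfg = SimConfig(seed=3, n_founders=1, n_generations=0,
                    field_shape=(20, 64, 64), cycle_mean_min=(17.0,),
                    cycle_sd_min=(0.5,), nucleus_radius_um=(5.0,),
                    p_express=1.0, memory_boost=0.0)
    truth = simulate_truth(cfg)
    movie = render_movie(truth, cfg)
    e = truth.expression.iloc[0]
    k = int((e.onset_s + 4 * 60) / cfg.frame_interval_s)
    vol = movie.data[k, 0].astype(float)
    obs, labels = detect_nuclei(vol, DetectionParams.nuclei_3d(min_size=300),
                                voxel_size_um=cfg.voxel_size_um, frame=k)
    mask = labels == obs[0].label
    return cfg, truth, vol, mask, k


def test_two_holes_in_a_diploid_nucleus(hole_fixture):
    cfg, truth, vol, mask, k = hole_fixture
    dark = detect_dark_regions(vol, mask,
                               DetectionParams.foci_3d(sensitivity_pct=130),
                               voxel_size_um=cfg.voxel_size_um, frame=k)
    assert len(dark) == 2
    sites = truth.sites[["x_um", "y_um", "z_um"]].to_numpy()
    for d in dark:
        err = np.linalg.norm(sites - np.array(d.centroid_um), axis=1).min()
        assert err <= 1.0      # within one (largest) voxel edge


def test_hole_free_nucleus_has_no_dark_regions(hole_fixture):
    cfg, truth, _, _, _ = hole_fixture
    silent = cfg.replace(perturbation="triptolide")
    truth2 = simulate_truth(silent)
    movie2 = render_movie(truth2, silent)
    k = movie2.n_frames // 3
    vol = movie2.data[k, 0].astype(float)
    obs, labels = detect_nuclei(vol, DetectionParams.nuclei_3d(min_size=300),
                                voxel_size_um=cfg.voxel_size_um, frame=k)
    mask = labels == obs[0].label
    dark = detect_dark_regions(vol, mask,
                               DetectionParams.foci_3d(sensitivity_pct=130),
                               voxel_size_um=cfg.voxel_size_um)
    assert dark == []


def test_dark_regions_require_a_mask(hole_fixture):
    cfg, _, vol, mask, _ = hole_fixture
    with pytest.raises(ValueError, match="empty"):
        detect_dark_regions(vol, np.zeros_like(mask),
                            DetectionParams.foci_3d(),
                            voxel_size_um=cfg.voxel_size_um)
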