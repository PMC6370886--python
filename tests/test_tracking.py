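"""Nucleus linking, division resolution and focus-to-nucleus assignment."""

import numpy as np
import pytest

from blastula import link_nuclei, assign_spots
from blastula.detection import NucleusObservation, SpotObservation
from blastula import benchmark


def _obs(frame, label, x, y, size=200, comps=1):
    return NucleusObservation(
        frame=frame, label=label, centroid_um=(x, y, 0.0),
        centroid_px=(y / 0.5, x / 0.5), size=size,
        mean_intensity=200.0, sd_intensity=10.0, component_count=comps)


def test_stationary_nucleus_gives_one_track():
    obs = {f: [_obs(f, 1, 30.0, 30.0)] for f in range(10)}
    tracks = link_nuclei(obs, max_step_um=6.0)
    assert len(tracks) == 1
    assert len(tracks[0].observations) == 10
    assert tracks[0].mother_track_id is None
    assert tracks[0].daughters is None


def test_gap_of_one_frame_is_bridged():
    obs = {f: [_obs(f, 1, 30.0, 30.0)] for f in range(10) if f != 4}
    tracks = link_nuclei(obs, max_step_um=6.0, max_gap_frames=1)
    assert len(tracks) == 1
    assert len(tracks[0].observations) == 9


def test_well_separated_neighbours_never_swap():
    """Two stationary nuclei 12 um apart cannot exchange identities when the
    step limit is 6 um."""
    obs = {f: [_obs(f, 1, 30.0, 30.0), _obs(f, 2, 42.0, 30.0)]
           for f in range(12)}
    tracks = link_nuclei(obs, max_step_um=6.0)
    assert len(tracks) == 2
    for t in tracks:
        xs = {o.centroid_um[0] for o in t.observations}
        assert len(xs) == 1         # each track stays on one nucleus


def test_division_opens_two_daughters_and_closes_mother():
    obs = {}
    for f in range(5):
        obs[f] = [_obs(f, 1, 30.0, 30.0)]
    for f in range(5, 10):
        obs[f] = [_obs(f, 1, 25.0, 30.0), _obs(f, 2, 35.0, 30.0)]
    tracks = link_nuclei(obs, max_step_um=6.0)
    mothers = [t for t in tracks if t.daughters is not None]
    assert len(mothers) == 1
    m = mothers[0]
    assert m.end_frame == 4
    kids = [t for t in tracks if t.mother_track_id == m.track_id]
    assert len(kids) == 2
    assert all(k.birth_frame == 5 for k in kids)


def test_duplicate_labels_in_a_frame_are_rejected():
    obs = {0: [_obs(0, 1, 10.0, 10.0), _obs(0, 1, 40.0, 40.0)]}
    with pytest.raises(ValueError, match="duplicate"):
        link_nuclei(obs)


def test_all_simulated_divisions_recovered_noise_free(noisefree_result,
                                                      noisefree_truth):
    tracks = noisefree_result.tracks
    recovered = sum(1 for t in tracks if t.daughters is not None)
    # the last simulated generation divides at the movie edge; every
    # interior division must be recovered as one mother with two daughters
    interior = (noisefree_truth.nuclei.mother_id >= 0).sum() // 2
    assert recovered >= interior
    for t in tracks:
        if t.daughters is not None:
            assert len(t.daughters) == 2


def test_track_count_doubles_across_generations(default_result,
                                                default_truth):
    tmap = benchmark.match_tracks(default_result.tracks, default_truth)
    gens = default_truth.nuclei.set_index("nucleus_id").generation
    per_gen = {}
    for tid, nid in tmap.items():
        g = int(gens[nid])
        per_gen.setdefault(g, set()).add(nid)
    assert len(per_gen[1]) >= 2 * len(per_gen[0]) * 0.9
    assert len(per_gen[2]) >= 2 * len(per_gen[1]) * 0.9


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _spot(frame, x, y, label=1):
    return SpotObservation(frame=frame, centroid_um=(x, y, 0.0),
                           centroid_px=(y / 0.5, x / 0.5), size=20,
                           volume_um3=float("nan"), peak_intensity=300.0,
                           integrated_intensity=5000.0, label=label)


def _label_disc(shape, cx_um, cy_um, r_um, label, vox=0.5):
    img = np.zeros(shape, dtype=np.int32)
    yy, xx = np.indices(shape).astype(float)
    img[((yy * vox - cy_um) ** 2 + (xx * vox - cx_um) ** 2) <= r_um ** 2] = label
    return img


def test_spot_at_nucleus_centroid_is_assigned():
    labels = {0: _label_disc((64, 64), 16.0, 16.0, 5.0, label=1)}
    obs = {0: [_obs(0, 1, 16.0, 16.0)]}
    tracks = link_nuclei(obs)
    spots = {0: [_spot(0, 16.0, 16.0)]}
    out = assign_spots(spots, tracks, labels, dilation_um=1.0,
                       voxel_size_um=(0.5, 0.5, 1.0))
    assert len(out) == 1
    assert out[0].track_id == tracks[0].track_id
    assert out[0].allele_index == 0


def test_distant_spot_stays_unassigned_not_dropped():
    labels = {0: _label_disc((64, 64), 16.0, 16.0, 5.0, label=1)}
    obs = {0: [_obs(0, 1, 16.0, 16.0)]}
    tracks = link_nuclei(obs)
    spots = {0: [_spot(0, 30.0, 30.0)]}
    out = assign_spots(spots, tracks, labels, dilation_um=1.0,
                       voxel_size_um=(0.5, 0.5, 1.0))
    assert len(out) == 1
    assert out[0].track_id == -1


def test_allele_index_is_stable_across_frames():
    labels = {f: _label_disc((64, 64), 16.0, 16.0, 6.0, label=1)
              for f in range(4)}
    obs = {f: [_obs(f, 1, 16.0, 16.0)] for f in range(4)}
    tracks = link_nuclei(obs)
    spots = {f: [_spot(f, 14.0, 16.0, label=1), _spot(f, 18.0, 16.0, label=2)]
             for f in range(4)}
    out = assign_spots(spots, tracks, labels, dilation_um=1.0,
                       voxel_size_um=(0.5, 0.5, 1.0))
    by_site = {}
    for a in out:
        by_site.setdefault(a.allele_index, set()).add(
            round(a.spot.centroid_um[0]))
    assert set(by_site) == {0, 1}
    for xs in by_site.values():
        assert len(xs) == 1     # each site keeps its own x position


def test_diploid_plateau_has_two_assignments_per_track(small_result):
    counts = small_result.counts
    assert len(counts) > 0
    assert (counts == 2).mean() >= 0.9


def test_assignment_completeness_on_default_movie(default_result,
                                                  default_truth):
    """At default noise, at least 95% of truth plateau foci end up assigned
    to the track matched to the right truth nucleus."""
    tmap = benchmark.match_tracks(default_result.tracks, default_truth)
    assigned = {}
    for a in default_result.assignments:
        if a.track_id >= 0:
            assigned.setdefault(a.frame, []).append(a)
    foci = default_truth.foci
    plateau = foci[foci.volume_um3 >= 0.8 * 16.0]
    hit = tot = 0
    for _, f in plateau.iterrows():
        tot += 1
        for a in assigned.get(int(f.frame), []):
            if tmap.get(a.track_id) == int(f.nucleus_id) and \
                    np.hypot(a.spot.centroid_um[0] - f.x_um,
                             a.spot.centroid_um[1] - f.y_um) < 2.0:
                hit += 1
                break
    assert hit / tot >= 0.95
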