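"""Chromatin features, phase segmentation and cycle measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blastula import (extract_features, segment_phases, measure_cycles,
                      lineage_cycles)
from blastula.cellcycle import (PhaseFeatures, PhaseTimeline, _GRAMMAR,
                                shannon_entropy_bits)
from blastula.tracking import NucleusTrack
from blastula.detection import NucleusObservation
from blastula import benchmark


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _track_with_mask(img, mask, frame=0):
    obs = NucleusObservation(
        frame=frame, label=1, centroid_um=(0, 0, 0), centroid_px=(0, 0),
        size=int(mask.sum()), mean_intensity=0.0, sd_intensity=0.0,
        component_count=1)
    return NucleusTrack(track_id=0, observations=[obs])


def test_uniform_mask_has_zero_sd_and_entropy():
    img = np.full((1, 32, 32), 100.0)
    labels = {0: np.ones((32, 32), dtype=np.int32)}
    track = _track_with_mask(img[0], labels[0])
    feats = extract_features(track, img, labels)
    assert feats[0].intensity_sd == 0.0
    assert feats[0].intensity_entropy == 0.0


def test_two_level_mask_has_one_bit_of_entropy():
    # half the pixels at each of two levels -> H = 1 bit exactly
    vals = np.array([0.0] * 50 + [63.9] * 50)
    assert shannon_entropy_bits(vals, 0.0, 64.0) == pytest.approx(1.0)


def test_entropy_of_uniform_histogram_is_log2_bins():
    vals = np.arange(64) + 0.5
    assert shannon_entropy_bits(vals, 0.0, 64.0) == pytest.approx(6.0)


def test_metaphase_texture_exceeds_s_phase_texture(default_result,
                                                   default_truth):
    """Median pixel SD in metaphase frames is above the S-phase median --
    the chromatin-compaction signal the classifier relies on."""
    tmap = benchmark.match_tracks(default_result.tracks, default_truth)
    sd = {"S": [], "metaphase": []}
    area = {"S": [], "metaphase": []}
    for tid, feats in default_result.features.items():
        if tid not in tmap:
            continue
        series = default_truth.phase_series(tmap[tid])
        for f in feats:
            ph = series.get(f.frame)
            if ph in sd and not f.missing:
                sd[ph].append(f.intensity_sd)
                area[ph].append(f.area_px)
    assert np.median(sd["metaphase"]) > np.median(sd["S"])
    assert np.median(area["metaphase"]) < np.median(area["S"])


def test_missing_mask_is_flagged_not_fatal():
    img = np.zeros((1, 16, 16))
    track = _track_with_mask(img[0], np.ones((16, 16), bool))
    feats = extract_features(track, img, {})     # no label image at frame 0
    assert feats[0].missing


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _features_from_labels(raw_labels):
    """Build PhaseFeatures whose raw classification reproduces ``raw_labels``."""
    rel_area = {"S": 0.95, "prophase": 0.6, "prometaphase": 0.33,
                "metaphase": 0.2, "telophase": 0.6, "anaphase": 0.3}
    out = []
    for i, lab in enumerate(raw_labels):
        out.append(PhaseFeatures(
            frame=i, track_id=0, area_px=1000 * rel_area[lab],
            intensity_sd=10.0, intensity_entropy=3.0,
            component_count=2 if lab == "anaphase" else 1))
    return out


def test_short_tracks_are_flagged_unsegmentable():
    feats = _features_from_labels(["S", "S"])
    assert segment_phases(feats) is None


def test_smoothed_labels_follow_the_phase_grammar():
    feats = _features_from_labels(
        ["S"] * 8 + ["prophase", "metaphase", "prophase", "anaphase"])
    tl = segment_phases(feats, frame_interval_s=51.0)
    order = {p: i for i, p in enumerate(_GRAMMAR)}
    idx = [order[l] for l in tl.labels]
    # only forward (possibly wrapping) transitions
    for a, b in zip(idx, idx[1:]):
        assert (b - a) % len(_GRAMMAR) <= 2


@given(st.lists(st.sampled_from(_GRAMMAR), min_size=3, max_size=25))
@settings(max_examples=40, deadline=None)
def test_grammar_smoothing_always_returns_legal_sequences(raw):
    tl = segment_phases(_features_from_labels(raw), frame_interval_s=51.0)
    order = {p: i for i, p in enumerate(_GRAMMAR)}
    idx = [order[l] for l in tl.labels]
    for a, b in zip(idx, idx[1:]):
        assert (b - a) % len(_GRAMMAR) <= 2


def test_noise_free_segmentation_errs_only_at_boundaries(noisefree_result,
                                                         noisefree_truth):
    """On noise-free movies every mislabelled frame sits within one frame of
    a truth phase boundary (sub-frame boundary placement is unknowable)."""
    scores = benchmark.phase_agreement(
        noisefree_result.timelines, noisefree_result.tracks, noisefree_truth,
        boundary_tol_frames=1)
    assert scores["accuracy_with_tolerance"] >= 0.97


def test_default_noise_segmentation_accuracy(default_result, default_truth):
    scores = benchmark.phase_agreement(
        default_result.timelines, default_result.tracks, default_truth)
    assert scores["accuracy"] >= 0.90


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------

def _timeline(labels, frame_interval_s=51.0):
    return PhaseTimeline(track_id=0, frames=np.arange(len(labels)),
                         labels=list(labels),
                         frame_interval_s=frame_interval_s)


def test_cycle_is_time_between_anaphases():
    # anaphase onsets at frames 2 and 16 with dt=50 -> cycle 700 s
    labels = (["S", "S", "anaphase", "telophase"] + ["S"] * 9
              + ["prophase", "prometaphase", "metaphase", "anaphase"])
    recs = measure_cycles(_timeline(labels, 50.0))
    assert len(recs) == 1
    assert recs[0].cycle_length_s == pytest.approx(700.0)
    assert recs[0].s_length_s == pytest.approx(9 * 50.0)
    assert recs[0].m_length_s == pytest.approx(recs[0].cycle_length_s
                                               - recs[0].s_length_s)


def test_track_without_division_yields_no_cycles():
    tl = _timeline(["telophase"] + ["S"] * 10)
    assert tl.anaphase_times_s() == []
    assert measure_cycles(tl) == []


def test_recovered_cycles_match_truth_within_one_frame(default_result,
                                                       default_truth):
    ce = benchmark.cycle_errors(default_result.cycles, default_result.tracks,
                                default_truth)
    assert len(ce) >= 20
    dt = default_truth.frame_interval_s
    assert (ce.cycle_err_s.abs() <= dt).mean() >= 0.95


def test_cycle_equals_s_plus_m_exactly(default_result):
    for r in default_result.cycles:
        assert r.cycle_length_s == pytest.approx(r.s_length_s + r.m_length_s)
        assert r.cycle_length_s > 0
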