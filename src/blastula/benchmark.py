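"""Scoring pipeline output against simulator ground truth.

Matching conventions: a detected nucleus corresponds to the truth nucleus
whose centre is nearest, within 1.2x the truth radius (the factor admits
late-anaphase masses that have moved off the nominal centre); tracks are
matched by per-frame majority vote; foci are matched one-to-one within a
physical tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .truth import GroundTruth
from .tracking import NucleusTrack


def match_tracks(tracks: list[NucleusTrack], truth: GroundTruth,
                 factor: float = 1.2) -> dict[int, int]:
    """Map track_id -> truth nucleus_id by per-frame nearest-centre vote."""
    dt = truth.frame_interval_s
    out: dict[int, int] = {}
    for t in tracks:
        votes: dict[int, int] = {}
        for o in t.observations:
            alive = truth.alive_at(o.frame * dt)
            if len(alive) == 0:
                continue
            d = np.hypot(alive.x_um - o.centroid_um[0],
                         alive.y_um - o.centroid_um[1])
            i = d.idxmin()
            if d[i] <= factor * alive.loc[i].radius_um:
                nid = int(alive.loc[i].nucleus_id)
                votes[nid] = votes.get(nid, 0) + 1
        if votes:
            out[t.track_id] = max(votes, key=votes.get)
    return out


def greedy_match_points(detected: np.ndarray, expected: np.ndarray,
                        tol_um: float) -> int:
    """Number of one-to-one matches between two point sets within ``tol_um``."""
    if len(detected) == 0 or len(expected) == 0:
        return 0
    tree = cKDTree(detected)
    dist, idx = tree.query(expected)
    used: set[int] = set()
    n = 0
    for d, i in sorted(zip(dist, idx)):
        if d <= tol_um and i not in used:
            used.add(int(i))
            n += 1
    return n


def foci_scores(spots_per_frame: dict, truth: GroundTruth,
                min_volume_frac: float = 0.5, tol_um: float = 1.5,
                peak_um3: float = 16.0) -> dict:
    """Precision/recall of 2D or 3D focus detections against truth foci.

    Recall counts truth foci at or above ``min_volume_frac`` of the plateau
    volume; precision counts detections farther than ``2 um`` from any truth
    focus (of any volume) as false.
    """
    foci = truth.foci
    tp = fn = fp = 0
    for f, spots in spots_per_frame.items():
        det = np.array([[s.centroid_um[0], s.centroid_um[1]] for s in spots]
                       ).reshape(-1, 2)
        tk = foci[foci.frame == f]
        big = tk[tk.volume_um3 >= min_volume_frac * peak_um3]
        exp = big[["x_um", "y_um"]].to_numpy()
        m = greedy_match_points(det, exp, tol_um)
        tp += m
        fn += len(exp) - m
        if len(det):
            allt = tk[["x_um", "y_um"]].to_numpy()
            if len(allt) == 0:
                fp += len(det)
            else:
                d, _ = cKDTree(allt).query(det)
                fp += int((d > 2.0).sum())
    recall = tp / max(tp + fn, 1)
    precision = tp / max(tp + fp, 1)
    return {"tp": tp, "fn": fn, "fp": fp,
            "recall": recall, "precision": precision}


def nuclei_scores(obs_per_frame: dict, truth: GroundTruth,
                  factor: float = 1.2) -> dict:
    """Precision/recall of nucleus detections against alive truth nuclei."""
    dt = truth.frame_interval_s
    tp = fn = fp = 0
    for f, obs in obs_per_frame.items():
        alive = truth.alive_at(f * dt)
        det = np.array([[o.centroid_um[0], o.centroid_um[1]] for o in obs]
                       ).reshape(-1, 2)
        matched_det: set[int] = set()
        for _, n in alive.iterrows():
            if len(det) == 0:
                fn += 1
                continue
            d = np.hypot(det[:, 0] - n.x_um, det[:, 1] - n.y_um)
            order = np.argsort(d)
            hit = None
            for i in order:
                if d[i] > factor * n.radius_um:
                    break
                if i not in matched_det:
                    hit = int(i)
                    break
            if hit is None:
                fn += 1
            else:
                matched_det.add(hit)
                tp += 1
        fp += len(det) - len(matched_det)
    return {"tp": tp, "fn": fn, "fp": fp,
            "recall": tp / max(tp + fn, 1),
            "precision": tp / max(tp + fp, 1)}


def phase_agreement(timelines: dict, tracks: list[NucleusTrack],
                    truth: GroundTruth,
                    boundary_tol_frames: int = 0) -> dict:
    """Frame-wise agreement of recovered phase labels with truth.

    With ``boundary_tol_frames`` > 0, a mismatched frame within that many
    frames of a truth phase boundary is excused (sub-frame boundary
    placement is not knowable from sampled data).
    """
    tmap = match_tracks(tracks, truth)
    by_id = {t.track_id: t for t in tracks}
    agree = total = excused = 0
    for tid, tl in timelines.items():
        if tl is None or tid not in tmap:
            continue
        nid = tmap[tid]
        truth_series = truth.phase_series(nid)
        for f, lab in zip(tl.frames, tl.labels):
            f = int(f)
            if f not in truth_series.index:
                continue
            total += 1
            if truth_series[f] == lab:
                agree += 1
            elif boundary_tol_frames > 0:
                near = [truth_series.get(f + d) for d in
                        range(-boundary_tol_frames, boundary_tol_frames + 1)]
                if lab in [x for x in near if x is not None]:
                    excused += 1
    return {"agree": agree, "total": total, "excused": excused,
            "accuracy": agree / max(total, 1),
            "accuracy_with_tolerance": (agree + excused) / max(total, 1)}


def cycle_errors(cycle_records, tracks: list[NucleusTrack],
                 truth: GroundTruth) -> pd.DataFrame:
    """Per-recovered-cycle comparison with the truth cycle of the matched
    nucleus: columns cycle/s/m recovered, truth, and their differences.

    Each record is matched within its own anaphase-to-anaphase window, so a
    track that (wrongly) spans a missed division still scores its measured
    cycle against the right truth nucleus.
    """
    by_id = {t.track_id: t for t in tracks}
    dt = truth.frame_interval_s
    nuc = truth.nuclei.set_index("nucleus_id")
    rows = []
    for r in cycle_records:
        t = by_id.get(r.track_id)
        if t is None:
            continue
        votes: dict[int, int] = {}
        for o in t.observations:
            if r.start_frame >= 0 and not (r.start_frame <= o.frame <= r.end_frame):
                continue
            alive = truth.alive_at(o.frame * dt)
            if len(alive) == 0:
                continue
            d = np.hypot(alive.x_um - o.centroid_um[0],
                         alive.y_um - o.centroid_um[1])
            i = d.idxmin()
            if d[i] <= 1.2 * alive.loc[i].radius_um:
                k = int(alive.loc[i].nucleus_id)
                votes[k] = votes.get(k, 0) + 1
        if not votes:
            continue
        nid = max(votes, key=votes.get)
        n = nuc.loc[nid]
        rows.append({
            "track_id": r.track_id, "nucleus_id": nid,
            "cycle_s": r.cycle_length_s, "cycle_truth_s": n.cycle_s,
            "cycle_err_s": r.cycle_length_s - n.cycle_s,
            "s_s": r.s_length_s, "s_truth_s": n.s_len_s,
            "s_err_s": r.s_length_s - n.s_len_s,
            "m_s": r.m_length_s, "m_truth_s": n.m_len_s,
        })
    return pd.DataFrame(rows)
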