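"""Linking nucleus observations into tracks and assigning foci to nuclei.

Blastula fields are sparse and nuclei essentially stationary between
divisions, so frame-to-frame greedy nearest-neighbour matching under a
physical step limit is sufficient (no global optimisation).  Divisions are
recognised when a tracked nucleus is succeeded by two detections within the
division radius — the canonical signature after anaphase, when the two
sister masses become separate objects; a preceding two-component (anaphase)
observation on the mother strengthens the candidate.

Transcription foci are assigned to the nucleus whose mask contains their
centroid, after dilating masks by a configurable margin so foci at the
nuclear rim are not lost; per-track allele indices are kept stable by
nearest-previous-site matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .detection import NucleusObservation, SpotObservation


@dataclass
class NucleusTrack:
    track_id: int
    mother_track_id: int | None = None
    daughters: tuple[int, int] | None = None
    observations: list[NucleusObservation] = field(default_factory=list)

    @property
    def birth_frame(self) -> int:
        return self.observations[0].frame

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.observations]

    def observation_at(self, frame: int) -> NucleusObservation | None:
        for o in self.observations:
            if o.frame == frame:
                return o
        return None

    def centroid_trace(self) -> np.ndarray:
        return np.array([o.centroid_um for o in self.observations])


@dataclass
class FocusAssignment:
    spot: SpotObservation
    track_id: int
    frame: int
    allele_index: int


# ---------------------------------------------------------------------------

def link_nuclei(observations_per_frame: dict[int, list[NucleusObservation]],
                max_step_um: float = 6.0,
                max_gap_frames: int = 1,
                division_radius_um: float | None = None,
                ) -> list[NucleusTrack]:
    """Link per-frame nucleus observations into division-resolved tracks.

    ``observations_per_frame`` maps frame index to the observations of that
    frame (any frames absent from the dict are treated as empty).  Returns
    completed tracks; every division produces a closed mother with exactly
    two daughter tracks.
    """
    if division_radius_um is None:
        division_radius_um = 1.4 * max_step_um
    frames = sorted(observations_per_frame)
    for f in frames:
        labels = [o.label for o in observations_per_frame[f]]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate observation labels in frame {f}")

    tracks: list[dict] = []
    active: list[dict] = []

    def new_track(obs, frame, mother=None):
        t = {"id": len(tracks), "mother": mother, "daughters": None,
             "obs": [obs], "last_frame": frame,
             "last_pos": np.asarray(obs.centroid_um)}
        tracks.append(t)
        active.append(t)
        return t

    for f in frames:
        dets = list(observations_per_frame[f])
        # retire tracks that have been unseen for too long
        still = [t for t in active
                 if f - t["last_frame"] <= max_gap_frames + 1 and t["daughters"] is None]
        active[:] = still
        cands = []
        for t in active:
            gap = f - t["last_frame"]
            if gap < 1:
                continue
            for j, d in enumerate(dets):
                dist = float(np.linalg.norm(t["last_pos"] - np.asarray(d.centroid_um)))
                if dist <= max_step_um * gap:
                    cands.append((dist, t["id"], j))
        cands.sort()
        matched_t: dict[int, int] = {}
        matched_d: dict[int, int] = {}
        for dist, tid, j in cands:
            if tid in matched_t or j in matched_d:
                continue
            matched_t[tid] = j
            matched_d[j] = tid

        by_id = {t["id"]: t for t in active}
        unmatched_dets = [j for j in range(len(dets)) if j not in matched_d]
        divided: set[int] = set()
        for j in list(unmatched_dets):
            if j in matched_d:
                continue
            pos = np.asarray(dets[j].centroid_um)
            best = None
            for t in active:
                gap = f - t["last_frame"]
                if t["id"] in divided or not 1 <= gap <= max_gap_frames + 1:
                    continue
                dist = float(np.linalg.norm(t["last_pos"] - pos))
                if dist > division_radius_um:
                    continue
                anaphase_hint = t["obs"][-1].component_count >= 2
                key = (not anaphase_hint, dist)
                if best is None or key < best[0]:
                    best = (key, t)
            if best is None:
                continue
            t = best[1]
            if t["id"] in matched_t:
                # mother matched one daughter this frame: reinterpret the
                # match as the second daughter of a division
                ja = matched_t.pop(t["id"])
                del matched_d[ja]
            else:
                # mother unmatched: need a second unmatched detection nearby
                partners = [jj for jj in range(len(dets))
                            if jj not in matched_d and jj != j
                            and np.linalg.norm(
                                t["last_pos"] - np.asarray(dets[jj].centroid_um))
                            <= division_radius_um]
                if not partners:
                    continue
                ja = min(partners, key=lambda jj: np.linalg.norm(
                    t["last_pos"] - np.asarray(dets[jj].centroid_um)))
            d1 = new_track(dets[ja], f, mother=t["id"])
            d2 = new_track(dets[j], f, mother=t["id"])
            t["daughters"] = (d1["id"], d2["id"])
            divided.add(t["id"])
            matched_d[ja] = -1
            matched_d[j] = -1
            active.remove(t)

        for tid, j in matched_t.items():
            t = by_id[tid]
            t["obs"].append(dets[j])
            t["last_frame"] = f
            t["last_pos"] = np.asarray(dets[j].centroid_um)
        for j in range(len(dets)):
            if j not in matched_d:
                new_track(dets[j], f)

    out = []
    for t in tracks:
        out.append(NucleusTrack(
            track_id=t["id"],
            mother_track_id=t["mother"],
            daughters=t["daughters"],
            observations=t["obs"],
        ))
    return out


# ---------------------------------------------------------------------------

def assign_spots(spots_per_frame: dict[int, list[SpotObservation]],
                 tracks: list[NucleusTrack],
                 label_images: dict[int, np.ndarray],
                 dilation_um: float = 1.0,
                 voxel_size_um=(1.0, 1.0, 1.0),
                 site_radius_um: float = 2.0,
                 ) -> list[FocusAssignment]:
    """Assign detected foci to tracked nuclei, frame by frame.

    A spot belongs to the track whose nucleus mask (dilated by
    ``dilation_um``) contains its centroid; spots farther than the dilation
    from every mask stay unassigned (``track_id == -1``) rather than being
    dropped.  ``allele_index`` is stable per track: each new spot joins the
    nearest previously seen focus site within ``site_radius_um``, or opens
    a new site.
    """
    label_to_track: dict[tuple[int, int], int] = {}
    for t in tracks:
        for o in t.observations:
            label_to_track[(o.frame, o.label)] = t.track_id

    vx, vy, vz = (tuple(voxel_size_um) + (1.0,))[:3]
    assignments: list[FocusAssignment] = []
    sites: dict[int, list[np.ndarray]] = {}

    for f in sorted(spots_per_frame):
        spots = spots_per_frame[f]
        if not spots:
            continue
        labels = label_images.get(f)
        nearest_lab = dist_um = None
        if labels is not None and labels.any():
            sampling = (vz, vy, vx) if labels.ndim == 3 else (vy, vx)
            dist_um, idx = ndi.distance_transform_edt(
                labels == 0, sampling=sampling, return_indices=True)
            nearest_lab = labels[tuple(idx)]
        for s in spots:
            tid = -1
            if nearest_lab is not None:
                pix = tuple(int(round(c)) for c in s.centroid_px)
                pix = tuple(np.clip(p, 0, n - 1)
                            for p, n in zip(pix, nearest_lab.shape))
                if dist_um[pix] <= dilation_um:
                    lab = int(nearest_lab[pix])
                    tid = label_to_track.get((f, lab), -1)
            s.nucleus_id = tid if tid >= 0 else None
            if tid < 0:
                assignments.append(FocusAssignment(
                    spot=s, track_id=-1, frame=f, allele_index=-1))
                continue
            pos = np.asarray(s.centroid_um)
            tr_sites = sites.setdefault(tid, [])
            if tr_sites:
                d = [float(np.linalg.norm(pos - q)) for q in tr_sites]
                k = int(np.argmin(d))
                if d[k] <= site_radius_um:
                    tr_sites[k] = 0.7 * tr_sites[k] + 0.3 * pos
                    assignments.append(FocusAssignment(
                        spot=s, track_id=tid, frame=f, allele_index=k))
                    continue
            tr_sites.append(pos.astype(float))
            assignments.append(FocusAssignment(
                spot=s, track_id=tid, frame=f, allele_index=len(tr_sites) - 1))
    return assignments


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: list[NucleusTrack]) -> pd.DataFrame:
    return pd.DataFrame([{
        "track_id": t.track_id,
        "mother_track_id": -1 if t.mother_track_id is None else t.mother_track_id,
        "birth_frame": t.birth_frame,
        "end_frame": t.end_frame,
        "n_obs": len(t.observations),
        "daughter_a": t.daughters[0] if t.daughters else -1,
        "daughter_b": t.daughters[1] if t.daughters else -1,
    } for t in tracks])


def assignments_to_frame(assignments: list[FocusAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "frame": a.frame, "track_id": a.track_id, "allele": a.allele_index,
        "x_um": a.spot.centroid_um[0], "y_um": a.spot.centroid_um[1],
        "z_um": a.spot.centroid_um[2], "size_px": a.spot.size,
        "volume_um3": a.spot.volume_um3,
        "peak": a.spot.peak_intensity,
    } for a in assignments])
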