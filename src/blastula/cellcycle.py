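"""Chromatin-texture features, cell-cycle phase segmentation and cycle
length measurement.

Cleavage-stage cycles alternate S-phase and mitosis with no gap phases, so
phase calls can be read off chromatin morphology alone: a decondensed
S-phase nucleus is large, dim and smooth; chromatin condensation through
prophase shrinks the 2D footprint while pixel intensity variance and
entropy rise; the metaphase plate is the smallest and most strongly
textured; anaphase appears as a two-component object whose masses separate.

Per-frame features (area, intensity SD, Shannon entropy of the intensity
histogram, component count) feed a rule-based classifier whose thresholds
are expressed relative to each track's own maximal (S-phase) footprint,
making them robust to illumination and magnification.  The raw frame
labels are then smoothed to the nearest legal phase sequence
(S -> prophase -> prometaphase -> metaphase -> anaphase -> telophase,
cyclically) by a minimal-edit dynamic programme.

Cycle length is the time between consecutive anaphase onsets, the standard
operational measure in chromatin-marker movies; S length is the duration of
the S run inside the cycle and M is the remainder, so cycle = S + M exactly
at frame quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import NucleusTrack

#: legal cyclic phase progression (one cell cycle, birth to division)
_GRAMMAR = ("telophase", "S", "prophase", "prometaphase", "metaphase", "anaphase")

#: phases short enough (at default M sub-phase fractions) to fall entirely
#: between two consecutive samples at ~51 s
_SKIPPABLE = ("prometaphase", "metaphase", "telophase")


@dataclass
class PhaseFeatures:
    frame: int
    track_id: int
    area_px: float              # 2D area or 3D voxel count of the mask
    intensity_sd: float
    intensity_entropy: float    # bits, 64-bin histogram over the frame range
    component_count: int
    elongation: float = 1.0
    missing: bool = False


@dataclass
class PhaseCalibration:
    """Classifier thresholds, as fractions of the track's S-phase footprint.

    ``area_s``/``area_pro``/``area_pm`` are the lower edges of the S,
    prophase and prometaphase bands of relative area (metaphase falls below
    ``area_pm``); relative area is area / 95th-percentile track area.
    """

    area_s: float = 0.88
    area_pro: float = 0.40
    area_pm: float = 0.28
    #: a condensed object at least this elongated is an anaphase pair
    anaphase_elongation: float = 1.7


@dataclass
class PhaseTimeline:
    track_id: int
    frames: np.ndarray                  # frame indices, ascending
    labels: list[str]
    frame_interval_s: float

    def anaphase_times_s(self) -> list[float]:
        """Start time of each anaphase run."""
        out = []
        prev = None
        for f, lab in zip(self.frames, self.labels):
            if lab == "anaphase" and prev != "anaphase":
                out.append(f * self.frame_interval_s)
            prev = lab
        return out

    def phase_at_frame(self, frame: int) -> str | None:
        idx = np.nonzero(self.frames == frame)[0]
        return self.labels[int(idx[0])] if len(idx) else None


@dataclass
class CellCycleRecord:
    track_id: int
    cycle_length_s: float
    s_length_s: float
    m_length_s: float
    generation: int = -1
    start_frame: int = -1       # anaphase-to-anaphase window, inclusive start
    end_frame: int = -1


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def shannon_entropy_bits(values: np.ndarray, lo: float, hi: float,
                         n_bins: int = 64) -> float:
    """Shannon entropy (bits) of an intensity histogram over ``[lo, hi]``."""
    if len(values) == 0 or hi <= lo:
        return 0.0
    hist, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def extract_features(track: NucleusTrack, chromatin: np.ndarray,
                     label_images: dict[int, np.ndarray],
                     n_bins: int = 64) -> list[PhaseFeatures]:
    """Per-frame chromatin features for one track.

    ``chromatin`` is the (T, Y, X) chromatin-channel image series (or
    (T, Z, Y, X) for 3D masks); ``label_images`` maps frame to the nucleus
    label mask produced by detection.  Frames whose mask is empty are
    returned flagged ``missing``.
    """
    out = []
    for obs in track.observations:
        f = obs.frame
        img = chromatin[f]
        labels = label_images.get(f)
        mask = labels == obs.label if labels is not None else None
        if mask is None or not mask.any():
            out.append(PhaseFeatures(frame=f, track_id=track.track_id,
                                     area_px=0.0, intensity_sd=0.0,
                                     intensity_entropy=0.0, component_count=1,
                                     elongation=1.0, missing=True))
            continue
        vals = np.asarray(img, dtype=float)[mask]
        out.append(PhaseFeatures(
            frame=f, track_id=track.track_id,
            area_px=float(mask.sum()),
            intensity_sd=float(vals.std()),
            intensity_entropy=shannon_entropy_bits(
                vals, float(img.min()), float(img.max()), n_bins),
            component_count=obs.component_count,
            elongation=getattr(obs, "elongation", 1.0),
        ))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _raw_labels(features: list[PhaseFeatures],
                cal: PhaseCalibration) -> list[str]:
    areas = np.array([f.area_px for f in features if not f.missing])
    ref = np.percentile(areas, 95) if len(areas) else 1.0
    labs = []
    for f in features:
        if f.missing:
            labs.append(None)
            continue
        rel = f.area_px / max(ref, 1.0)
        if f.component_count >= 2 or \
                (rel < cal.area_s and f.elongation >= cal.anaphase_elongation):
            labs.append("anaphase")
            continue
        if rel >= cal.area_s:
            labs.append("S")
        elif rel >= cal.area_pro:
            labs.append("prophase")
        elif rel >= cal.area_pm:
            labs.append("prometaphase")
        else:
            labs.append("metaphase")
    # a leading condensed-looking run before the first S frame is the
    # re-expanding telophase of a newborn nucleus, not mitotic entry
    first_s = next((i for i, l in enumerate(labs) if l == "S"), None)
    if first_s is not None:
        for i in range(first_s):
            if labs[i] in ("prophase", "prometaphase", "metaphase"):
                labs[i] = "telophase"
    return labs


def _grammar_smooth(labs: list[str], frames=None) -> list[str]:
    """Minimal-edit projection onto the legal cyclic phase sequence.

    States advance only forward through the cyclic grammar.  Between
    consecutive observations the phase may advance by up to two states per
    elapsed frame (mitotic sub-phases are shorter than one frame interval,
    so one of them can fall entirely between samples); unknown (None)
    frames carry no cost and adopt the interpolated phase.
    """
    n_states = len(_GRAMMAR)
    n = len(labs)
    if n == 0:
        return []
    if frames is None:
        frames = np.arange(n)
    INF = 1e18
    cost = np.full((n, n_states), INF)
    back = np.zeros((n, n_states), dtype=int)
    for s in range(n_states):
        cost[0, s] = 0 if (labs[0] is None or labs[0] == _GRAMMAR[s]) else 1
    for i in range(1, n):
        gap = max(int(frames[i]) - int(frames[i - 1]), 1)
        max_adv = 2 if gap == 1 else min(2 * gap, n_states - 1)
        for s in range(n_states):
            c_here = 0 if (labs[i] is None or labs[i] == _GRAMMAR[s]) else 1
            best = INF
            arg = s
            for k in range(max_adv + 1):
                if gap == 1 and k == 2 and _GRAMMAR[(s - 1) % n_states] \
                        not in _SKIPPABLE:
                    continue    # only sub-frame-short phases can be skipped
                p = (s - k) % n_states
                if cost[i - 1, p] < best:
                    best = cost[i - 1, p]
                    arg = p
            cost[i, s] = best + c_here
            back[i, s] = arg
    s = int(np.argmin(cost[-1]))
    out = [None] * n
    for i in range(n - 1, -1, -1):
        out[i] = _GRAMMAR[s]
        s = int(back[i, s])
    return out


def segment_phases(features: list[PhaseFeatures],
                   calibration: PhaseCalibration | None = None,
                   frame_interval_s: float = 51.0) -> PhaseTimeline | None:
    """Classify each frame of one track into a cell-cycle phase.

    Returns ``None`` (flagged, not an error) for tracks shorter than 3
    frames, which cannot be segmented meaningfully.
    """
    if len(features) < 3:
        return None
    cal = calibration or PhaseCalibration()
    frames = np.array([f.frame for f in features])
    labs = _grammar_smooth(_raw_labels(features, cal), frames)
    return PhaseTimeline(
        track_id=features[0].track_id,
        frames=np.array([f.frame for f in features]),
        labels=labs,
        frame_interval_s=frame_interval_s,
    )


# ---------------------------------------------------------------------------
# cycle measurement
# ---------------------------------------------------------------------------

def measure_cycles(timeline: PhaseTimeline,
                   frame_interval_s: float | None = None,
                   ) -> list[CellCycleRecord]:
    """Anaphase-to-anaphase cycle lengths within one timeline.

    Requires at least two anaphase onsets (e.g. a timeline concatenated
    along a mother-daughter chain); otherwise returns an empty list.
    S length is the duration of the S run between the two anaphases and
    M = cycle - S, so the identity cycle = S + M holds exactly.
    """
    dt = frame_interval_s or timeline.frame_interval_s
    onsets = []
    prev = None
    for i, lab in enumerate(timeline.labels):
        if lab == "anaphase" and prev != "anaphase":
            onsets.append(i)
        prev = lab
    records = []
    for a, b in zip(onsets, onsets[1:]):
        f1, f2 = int(timeline.frames[a]), int(timeline.frames[b])
        cycle = (f2 - f1) * dt
        n_s = sum(1 for i in range(a + 1, b + 1)
                  if timeline.labels[i] == "S")
        s_len = n_s * dt
        records.append(CellCycleRecord(
            track_id=timeline.track_id,
            cycle_length_s=cycle, s_length_s=s_len,
            m_length_s=cycle - s_len,
            start_frame=f1, end_frame=f2,
        ))
    return records


def _division_boundaries(tl: PhaseTimeline) -> list[int]:
    """Frames at which an interior division completed: one past the last
    metaphase/anaphase frame of each mitosis that is followed by re-entry
    into telophase or S within the same (unsplit) track."""
    out = []
    labels, frames = tl.labels, tl.frames
    for i in range(len(labels) - 1):
        if labels[i] in ("metaphase", "anaphase") and \
                labels[i + 1] in ("telophase", "S"):
            out.append(int(frames[i]) + 1)
    return out


def _trailing_anaphase_frame(tl: PhaseTimeline) -> int | None:
    """First frame of the anaphase run that ends the timeline, if any."""
    if not tl.labels or tl.labels[-1] != "anaphase":
        return None
    i = len(tl.labels) - 1
    while i > 0 and tl.labels[i - 1] == "anaphase":
        i -= 1
    return int(tl.frames[i])


def lineage_cycles(tracks: list[NucleusTrack],
                   timelines: dict[int, PhaseTimeline],
                   frame_interval_s: float = 51.0,
                   n_frames: int | None = None) -> list[CellCycleRecord]:
    """One cycle record per daughter track with a measurable full cycle.

    The cycle of a daughter runs from the frame it first appears as a
    separate object (just after its mother's anaphase) to the frame its own
    daughters appear — or, for the last simulated generation, to the frame
    after its final observation, when the nucleus vanished into its own
    anaphase.  Both cycle ends therefore sit on the same sampling
    convention and their sub-frame offsets cancel.  Tracks still alive at
    the end of the movie (``n_frames``) yield no record.
    """
    by_id = {t.track_id: t for t in tracks}

    def depth(t: NucleusTrack) -> int:
        d = 0
        while t.mother_track_id is not None:
            t = by_id[t.mother_track_id]
            d += 1
        return d

    records = []
    for t in tracks:
        if t.mother_track_id is None:
            continue
        tl_d = timelines.get(t.track_id)
        if tl_d is None:
            continue
        a1 = t.birth_frame
        mother = by_id.get(t.mother_track_id)
        if mother is not None and mother.daughters is not None:
            # siblings are born at the same division: the first-resolved
            # one pins the shared birth frame
            a1 = min(a1, *(by_id[d].birth_frame for d in mother.daughters
                           if d in by_id))
        tl_m = timelines.get(t.mother_track_id)
        if tl_m is not None and tl_m.labels and \
                tl_m.labels[-1] in ("metaphase", "anaphase"):
            # the mother's sampled mitotic exit pins the birth more
            # precisely than the frame the daughters were first resolved
            cand = int(tl_m.frames[-1]) + 1
            if 0 <= a1 - cand <= 3:
                a1 = cand
        # divisions the tracker failed to split show up as interior
        # mitosis -> S/telophase transitions in the timeline
        interior = _division_boundaries(tl_d)
        if t.daughters is not None:
            final = min(by_id[d].birth_frame for d in t.daughters)
        elif n_frames is None or t.end_frame < n_frames - 1:
            # vanished mid-movie: score the division only if its anaphase
            # pair was actually sampled; otherwise the division moment is
            # unobserved and the cycle is right-censored
            fa = _trailing_anaphase_frame(tl_d)
            final = fa + 1 if fa is not None else None
        else:
            final = None                    # movie ended before division
        bounds = [a1] + [b for b in interior if b >= a1 + 4]
        if final is not None and final >= bounds[-1] + 4:
            bounds.append(final)
        gen0 = depth(t)
        for seg, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
            cycle = (b2 - b1) * frame_interval_s
            n_s = sum(1 for fr, lab in zip(tl_d.frames, tl_d.labels)
                      if lab == "S" and b1 <= fr <= b2)
            s_len = n_s * frame_interval_s
            records.append(CellCycleRecord(
                track_id=t.track_id, cycle_length_s=cycle,
                s_length_s=s_len, m_length_s=cycle - s_len,
                generation=gen0 + seg, start_frame=b1, end_frame=b2))
    return records


def cycles_to_frame(records: list[CellCycleRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "track_id": r.track_id, "cycle_length_s": r.cycle_length_s,
        "s_length_s": r.s_length_s, "m_length_s": r.m_length_s,
        "generation": r.generation,
    } for r in records])


def features_to_frame(features: list[PhaseFeatures]) -> pd.DataFrame:
    return pd.DataFrame([{
        "frame": f.frame, "track_id": f.track_id, "area_px": f.area_px,
        "intensity_sd": f.intensity_sd, "entropy_bits": f.intensity_entropy,
        "component_count": f.component_count, "missing": f.missing,
    } for f in features])


def timelines_to_frame(timelines: dict[int, PhaseTimeline]) -> pd.DataFrame:
    rows = []
    for tid, tl in timelines.items():
        if tl is None:
            continue
        for f, lab in zip(tl.frames, tl.labels):
            rows.append({"track_id": tid, "frame": int(f), "phase": lab})
    return pd.DataFrame(rows)
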