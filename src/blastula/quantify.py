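"""Per-nucleus and per-frame expression quantities and compartment volume
dynamics.

From focus-to-nucleus assignments and phase timelines this module derives
the read-outs used to characterise the first wave of genome activation:
when each nucleus switches on (onset time, phase at onset, delay from
S-phase entry), how long its transcript signal persists (expression span),
how many foci it carries, what fraction of nuclei express at each frame,
and how the focus (or chromatin-hole) volume evolves through the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import FocusAssignment, NucleusTrack
from .cellcycle import PhaseTimeline


@dataclass
class ExpressionRecord:
    track_id: int
    onset_time_s: float
    end_time_s: float
    span_s: float
    onset_frame: int
    end_frame: int
    onset_phase: str | None     # None when the track has no phase timeline
    onset_delay_s: float        # onset - S-phase entry; NaN when unphased
    foci_count: int             # max simultaneous distinct foci
    expressed: bool = True


@dataclass
class VolumeSeries:
    track_id: int
    allele_index: int
    times_s: np.ndarray         # aligned to first detection
    volumes_um3: np.ndarray
    peak_volume_um3: float
    plateau_duration_s: float   # longest run within 80% of peak


@dataclass
class FrameSummary:
    frame: int
    n_nuclei: int
    n_expressing: int
    n_new_expressing: int
    fraction_expressing: float


# ---------------------------------------------------------------------------

def _runs(frames: list[int], bridge: int = 1):
    """Split sorted frame indices into runs, bridging gaps <= ``bridge``."""
    runs = []
    cur = [frames[0]]
    for f in frames[1:]:
        if f - cur[-1] <= 1 + bridge:
            cur.append(f)
        else:
            runs.append(cur)
            cur = [f]
    runs.append(cur)
    return runs


def expression_records(assignments: list[FocusAssignment],
                       timelines: dict[int, PhaseTimeline],
                       min_persist_frames: int = 2,
                       frame_interval_s: float = 51.0,
                       ) -> list[ExpressionRecord]:
    """One expression record per track with a persistent focus signal.

    Onset is the first frame of the first run of at least
    ``min_persist_frames`` frames carrying an assigned focus (single-frame
    blips are discarded as noise); the end is the last frame of the last
    such run, so residual signal detected into prophase/metaphase counts
    toward the span.  Tracks without a phase timeline yield records flagged
    unphased (``onset_phase is None``).
    """
    from .cellcycle import _division_boundaries
    per_track: dict[int, dict[int, set]] = {}
    for a in assignments:
        if a.track_id < 0:
            continue
        per_track.setdefault(a.track_id, {}).setdefault(a.frame, set()).add(
            a.allele_index)
    records = []
    for tid, by_frame in sorted(per_track.items()):
        frames = sorted(by_frame)
        tl = timelines.get(tid)
        # one record per cycle: when the timeline shows an interior
        # division, focus frames on either side belong to different cycles
        bounds = _division_boundaries(tl) if tl is not None else []
        segments = []
        cur = []
        for f in frames:
            if cur and any(cur[-1] < b <= f for b in bounds):
                segments.append(cur)
                cur = []
            cur.append(f)
        if cur:
            segments.append(cur)
        for seg in segments:
            good = [r for r in _runs(seg) if len(r) >= min_persist_frames]
            if not good:
                continue
            onset_f = good[0][0]
            end_f = good[-1][-1]
            onset_phase = None
            delay = float("nan")
            if tl is not None:
                onset_phase = tl.phase_at_frame(onset_f)
                s_frames = [int(f) for f, lab in zip(tl.frames, tl.labels)
                            if lab == "S" and f <= onset_f]
                if s_frames:
                    # start of the S run the onset belongs to
                    s_start = s_frames[-1]
                    for f in reversed(s_frames[:-1]):
                        if s_start - f == 1:
                            s_start = f
                        else:
                            break
                    delay = (onset_f - s_start) * frame_interval_s
            foci_count = max(len(by_frame[f]) for r in good for f in r
                             if f in by_frame)
            records.append(ExpressionRecord(
                track_id=tid,
                onset_time_s=onset_f * frame_interval_s,
                end_time_s=end_f * frame_interval_s,
                span_s=(end_f - onset_f) * frame_interval_s,
                onset_frame=onset_f, end_frame=end_f,
                onset_phase=onset_phase, onset_delay_s=delay,
                foci_count=foci_count,
            ))
    return records


def frame_summaries(records: list[ExpressionRecord],
                    tracks: list[NucleusTrack],
                    n_frames: int | None = None) -> list[FrameSummary]:
    """Per-frame counts of alive, expressing and newly expressing nuclei."""
    if n_frames is None:
        n_frames = 1 + max((t.end_frame for t in tracks), default=0)
    out = []
    for f in range(n_frames):
        alive = sum(1 for t in tracks if t.birth_frame <= f <= t.end_frame)
        expressing = sum(1 for r in records
                         if r.onset_frame <= f <= r.end_frame)
        new = sum(1 for r in records if r.onset_frame == f)
        out.append(FrameSummary(
            frame=f, n_nuclei=alive, n_expressing=expressing,
            n_new_expressing=new,
            fraction_expressing=expressing / alive if alive else 0.0,
        ))
    return out


def volume_series(assignments: list[FocusAssignment],
                  frame_interval_s: float = 51.0,
                  plateau_frac: float = 0.8) -> list[VolumeSeries]:
    """Per-allele focus volume over time, aligned to first detection.

    Requires 3D assignments (``volume_um3`` populated).  The plateau is the
    longest run of consecutive frames within ``plateau_frac`` of the peak;
    a single-frame series has a defined peak and a one-frame plateau.  The
    same operation serves dark-region (chromatin hole) series.
    """
    per_key: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for a in assignments:
        if a.track_id < 0:
            continue
        v = a.spot.volume_um3
        if v is None or np.isnan(v):
            continue
        per_key.setdefault((a.track_id, a.allele_index), []).append(
            (a.frame, float(v)))
    out = []
    for (tid, allele), seq in sorted(per_key.items()):
        seq.sort()
        frames = np.array([f for f, _ in seq])
        vols = np.array([v for _, v in seq])
        peak = float(vols.max())
        near = vols >= plateau_frac * peak
        best = run = 0
        for i in range(len(vols)):
            if near[i] and (i == 0 or frames[i] - frames[i - 1] == 1
                            and near[i - 1]):
                run += 1
            elif near[i]:
                run = 1
            else:
                run = 0
            best = max(best, run)
        out.append(VolumeSeries(
            track_id=tid, allele_index=allele,
            times_s=(frames - frames[0]) * frame_interval_s,
            volumes_um3=vols,
            peak_volume_um3=peak,
            plateau_duration_s=max(best, 1) * frame_interval_s,
        ))
    return out


def foci_counts(records: list[ExpressionRecord]) -> pd.Series:
    """Max simultaneous foci per expressing track (index = track_id)."""
    return pd.Series({r.track_id: r.foci_count for r in records
                      if r.expressed}, dtype=int)


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def records_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "track_id": r.track_id, "onset_s": r.onset_time_s,
        "end_s": r.end_time_s, "span_s": r.span_s,
        "onset_frame": r.onset_frame, "end_frame": r.end_frame,
        "onset_phase": r.onset_phase, "onset_delay_s": r.onset_delay_s,
        "foci_count": r.foci_count, "expressed": r.expressed,
    } for r in records])


def summaries_to_frame(summaries: list[FrameSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "frame": s.frame, "n_nuclei": s.n_nuclei,
        "n_expressing": s.n_expressing,
        "n_new_expressing": s.n_new_expressing,
        "fraction_expressing": s.fraction_expressing,
    } for s in summaries])


def volumes_to_frame(series: list[VolumeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, v in zip(s.times_s, s.volumes_um3):
            rows.append({"track_id": s.track_id, "allele": s.allele_index,
                         "t_s": float(t), "volume_um3": float(v),
                         "peak_um3": s.peak_volume_um3,
                         "plateau_s": s.plateau_duration_s})
    return pd.DataFrame(rows)
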