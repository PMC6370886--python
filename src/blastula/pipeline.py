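"""End-to-end orchestration: movie -> detection -> tracking -> phases ->
quantification -> statistics, with a reproducible run directory.

The pipeline is deterministic given its configuration (no stage uses
randomness), so re-running the same movie and config produces bit-identical
tables; a manifest records the config hash and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .movie import Movie
from .detection import (DetectionParams, max_project, detect_spots,
                        detect_nuclei, spots_to_frame, nuclei_to_frame)
from .tracking import (link_nuclei, assign_spots, tracks_to_frame,
                       assignments_to_frame)
from .cellcycle import (PhaseCalibration, extract_features, segment_phases,
                        lineage_cycles, cycles_to_frame, features_to_frame,
                        timelines_to_frame)
from .quantify import (expression_records, frame_summaries, volume_series,
                       foci_counts, records_to_frame, summaries_to_frame,
                       volumes_to_frame)
from . import stats as bstats

log = logging.getLogger("blastula.pipeline")


@dataclass
class PipelineConfig:
    chromatin_channel: str = "h2b"
    transcript_channel: str = "mo"
    mode: str = "2d"                        # 2d (MIP) | 3d (full volumes)
    nuclei_params: DetectionParams = field(
        default_factory=lambda: DetectionParams.nuclei_2d(
            min_size=25, max_size=700))
    foci_params: DetectionParams = field(
        default_factory=DetectionParams.foci_2d)
    max_step_um: float = 6.0
    max_gap_frames: int = 1
    dilation_um: float = 1.0
    min_persist_frames: int = 2
    calibration: PhaseCalibration = field(default_factory=PhaseCalibration)
    seed: int = 0

    def validate(self, movie: Movie | None = None) -> None:
        self.nuclei_params.validate()
        self.foci_params.validate()
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.max_step_um <= 0 or self.dilation_um < 0:
            raise ValueError("invalid tracking parameters")
        if self.min_persist_frames < 1:
            raise ValueError("min_persist_frames must be >= 1")
        if movie is not None:
            for ch in (self.chromatin_channel, self.transcript_channel):
                movie.channel_index(ch)     # raises for unknown channels

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("nuclei_params", "foci_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = DetectionParams(**d[key])
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = PhaseCalibration(**d["calibration"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def for_mode(self, mode: str) -> "PipelineConfig":
        """Config with detection presets switched to the requested mode."""
        if mode == self.mode:
            return self
        if mode == "3d":
            return dataclasses.replace(
                self, mode="3d",
                nuclei_params=DetectionParams.nuclei_3d(),
                foci_params=DetectionParams.foci_3d())
        return dataclasses.replace(
            self, mode="2d",
            nuclei_params=DetectionParams.nuclei_2d(min_size=25, max_size=700),
            foci_params=DetectionParams.foci_2d())


@dataclass
class PipelineResult:
    movie: Movie
    config: PipelineConfig
    nuclei_obs: dict
    label_images: dict
    spots: dict
    tracks: list
    assignments: list
    features: dict
    timelines: dict
    cycles: list
    records: list
    summaries: list
    volumes: list
    counts: pd.Series
    stats: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        all_obs = [o for obs in self.nuclei_obs.values() for o in obs]
        all_spots = [s for sp in self.spots.values() for s in sp]
        all_feats = [f for fs in self.features.values() for f in fs]
        return {
            "nuclei": nuclei_to_frame(all_obs),
            "spots": spots_to_frame(all_spots),
            "tracks": tracks_to_frame(self.tracks),
            "assignments": assignments_to_frame(self.assignments),
            "features": features_to_frame(all_feats),
            "phases": timelines_to_frame(self.timelines),
            "cycles": cycles_to_frame(self.cycles),
            "expression": records_to_frame(self.records),
            "frame_summary": summaries_to_frame(self.summaries),
            "volumes": volumes_to_frame(self.volumes),
        }


def run_pipeline(movie: Movie | str | Path,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run detect -> track -> segment -> quantify -> stats on one movie.

    ``movie`` may be a :class:`Movie` or a path to a saved one.  When
    ``out_dir`` is given, all module tables, a stats report and a
    provenance manifest are written there.
    """
    t_start = time.time()
    if not isinstance(movie, Movie):
        movie = Movie.load(movie)
    config = config or PipelineConfig()
    config.validate(movie)
    dt = movie.frame_interval_s
    vox = movie.voxel_size_um
    n_frames = movie.n_frames

    def _stage(name, t0):
        log.info("stage %-10s %.2fs", name, time.time() - t0)

    # --- detection -------------------------------------------------------
    t0 = time.time()
    if config.mode == "2d":
        chrom = max_project(movie, config.chromatin_channel).data[:, 0, 0]
        trans = max_project(movie, config.transcript_channel).data[:, 0, 0]
    else:
        chrom = movie.data[:, movie.channel_index(config.chromatin_channel)]
        trans = movie.data[:, movie.channel_index(config.transcript_channel)]
    nuclei_obs, label_images, spots = {}, {}, {}
    for f in range(n_frames):
        obs, labels = detect_nuclei(chrom[f], config.nuclei_params,
                                    voxel_size_um=vox, frame=f)
        nuclei_obs[f] = obs
        label_images[f] = labels
        spots[f] = detect_spots(trans[f], config.foci_params,
                                voxel_size_um=vox, frame=f)
    _stage("detect", t0)

    # --- tracking --------------------------------------------------------
    t0 = time.time()
    tracks = link_nuclei(nuclei_obs, max_step_um=config.max_step_um,
                         max_gap_frames=config.max_gap_frames)
    assignments = assign_spots(spots, tracks, label_images,
                               dilation_um=config.dilation_um,
                               voxel_size_um=vox)
    _stage("track", t0)

    # --- cell-cycle segmentation ----------------------------------------
    t0 = time.time()
    features, timelines = {}, {}
    for t in tracks:
        feats = extract_features(t, chrom, label_images)
        features[t.track_id] = feats
        tl = segment_phases(feats, config.calibration, frame_interval_s=dt)
        if tl is not None:
            timelines[t.track_id] = tl
    cycles = lineage_cycles(tracks, timelines, frame_interval_s=dt,
                            n_frames=n_frames)
    _stage("segment", t0)

    # --- quantification --------------------------------------------------
    t0 = time.time()
    records = expression_records(assignments, timelines,
                                 min_persist_frames=config.min_persist_frames,
                                 frame_interval_s=dt)
    summaries = frame_summaries(records, tracks, n_frames=n_frames)
    volumes = volume_series(assignments, frame_interval_s=dt)
    counts = foci_counts(records)
    _stage("quantify", t0)

    # --- statistics ------------------------------------------------------
    t0 = time.time()
    stats: dict = {"n_tracks": len(tracks), "n_records": len(records),
                   "n_cycles": len(cycles)}
    for against in ("cycle", "S", "M"):
        c = bstats.correlate_lengths(records, cycles, against=against)
        stats[f"span_vs_{against}"] = dataclasses.asdict(c)
    if len(counts):
        stats["foci_count_median"] = float(counts.median())
        stats["foci_count_mode"] = int(counts.mode().iloc[0])
    _stage("stats", t0)

    result = PipelineResult(
        movie=movie, config=config, nuclei_obs=nuclei_obs,
        label_images=label_images, spots=spots, tracks=tracks,
        assignments=assignments, features=features, timelines=timelines,
        cycles=cycles, records=records, summaries=summaries,
        volumes=volumes, counts=counts, stats=stats)

    if out_dir is not None:
        write_run_dir(result, out_dir, runtime_s=time.time() - t_start)
    return result


def write_run_dir(result: PipelineResult, out_dir, runtime_s: float = 0.0
                  ) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables().items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=1, default=_jsonable)
    cfg = result.config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": result.config.seed,
        "versions": _versions(),
        "movie_shape": list(result.movie.data.shape),
        "runtime_s": round(runtime_s, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)
    return out


def _versions() -> dict:
    import scipy
    import skimage
    from . import __version__ as pkg_version
    return {"blastula": pkg_version, "numpy": np.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__,
            "pandas": pd.__version__}


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
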