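"""Shared plumbing for the analysis drivers: canonical run locations and
a cached default simulation (simulate once in 01, reuse downstream)."""

from pathlib import Path

from blastula import (SimConfig, simulate_truth, render_movie, Movie,
                      GroundTruth)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

DEFAULT_SEED = 1


def default_movie_and_truth():
    """The default diploid embryo movie, simulated on first use and cached
    under scratch/ for the later drivers."""
    movie_path = SCRATCH / "default" / "movie.tif"
    truth_dir = SCRATCH / "default" / "truth"
    cfg = SimConfig(seed=DEFAULT_SEED)
    if movie_path.exists() and (truth_dir / "nuclei.csv").exists():
        return Movie.load(movie_path), GroundTruth.read(truth_dir), cfg
    truth = simulate_truth(cfg)
    movie = render_movie(truth, cfg)
    movie_path.parent.mkdir(parents=True, exist_ok=True)
    movie.save(movie_path)
    truth.write(truth_dir)
    return movie, truth, cfg


def out_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
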