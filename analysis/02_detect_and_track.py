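"""Detect nuclei and transcription foci, link tracks, and score both
against the simulator's ground truth.

Expected outcome: >= 95% precision and recall for foci (at plateau volume)
and for nuclei, with essentially every interior division recovered as one
mother splitting into two daughters.
"""

import json

from blastula import run_pipeline, PipelineConfig
from blastula import benchmark
from common import default_movie_and_truth, out_dir


def main():
    movie, truth, _ = default_movie_and_truth()
    out = out_dir("02_detect_track")

    result = run_pipeline(movie, PipelineConfig(), out_dir=out / "run")

    foci = benchmark.foci_scores(
        {f: [a.spot for a in result.assignments if a.frame == f]
         for f in range(movie.n_frames)}, truth)
    nuclei = benchmark.nuclei_scores(result.nuclei_obs, truth)
    divisions = sum(1 for t in result.tracks if t.daughters is not None)
    truth_div = int((truth.nuclei.mother_id >= 0).sum()) // 2

    scores = {"foci": foci, "nuclei": nuclei,
              "divisions_recovered": divisions,
              "interior_truth_divisions": truth_div}
    with open(out / "scores.json", "w") as fh:
        json.dump(scores, fh, indent=1)

    print(f"foci:   recall {foci['recall']:.3f}  precision "
          f"{foci['precision']:.3f}")
    print(f"nuclei: recall {nuclei['recall']:.3f}  precision "
          f"{nuclei['precision']:.3f}")
    print(f"tracks: {len(result.tracks)}, divisions recovered {divisions} "
          f"(interior truth divisions: {truth_div}; the final generation "
          f"divides at the movie edge)")


if __name__ == "__main__":
    main()
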