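"""Mother-to-daughter expression memory and the diploid/tetraploid
comparison.

Expected outcomes: with the generator's default +0.15 memory boost the
daughter on-rate is higher after an expressing mother (the association test
on one desk-scale movie is underpowered, so the table and rates are the
primary read-out); tetraploid embryos carry twice the foci of diploids but
do not activate earlier.
"""

import json

from blastula import (SimConfig, simulate_truth, render_movie, run_pipeline,
                      PipelineConfig, foci_counts)
from blastula import stats as bstats
from common import default_movie_and_truth, out_dir

PLOIDY_KW = dict(n_founders=8, n_generations=1, field_shape=(20, 160, 160),
                 cycle_mean_min=(13.0, 17.0), cycle_sd_min=(1.0, 1.3),
                 p_express=0.9, memory_boost=0.05)


def main():
    movie, truth, _ = default_movie_and_truth()
    out = out_dir("06_memory_ploidy")
    report = {}

    result = run_pipeline(movie, PipelineConfig())
    mem = bstats.memory_analysis(result.tracks, result.records)
    report["memory"] = {
        "contingency_mother_on_off_x_daughter_on_off":
            mem.contingency.tolist(),
        "test": mem.test, "p": mem.p, "valid": mem.valid,
        "daughter_span_p": None if mem.span_comparison is None
        else mem.span_comparison.p,
    }

    runs = {}
    for ploidy in (2, 4):
        cfg = SimConfig(seed=21, ploidy=ploidy, **PLOIDY_KW)
        runs[ploidy] = run_pipeline(render_movie(simulate_truth(cfg), cfg),
                                    PipelineConfig())
    onsets = {p: [r.onset_time_s for r in runs[p].records] for p in (2, 4)}
    cmp = bstats.ploidy_comparison(
        foci_counts(runs[2].records), foci_counts(runs[4].records),
        onsets_diploid=onsets[2], onsets_tetraploid=onsets[4])
    report["ploidy"] = {
        "modal_count_diploid": cmp["modal_count_diploid"],
        "modal_count_tetraploid": cmp["modal_count_tetraploid"],
        "modal_ratio": cmp["modal_ratio"],
        "count_p": cmp["count_comparison"].p,
        "onset_p": cmp["onset_comparison"].p,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    t = mem.contingency
    on_rate_m_on = t[0, 0] / max(t[0].sum(), 1)
    on_rate_m_off = t[1, 0] / max(t[1].sum(), 1)
    print(f"memory: daughter on-rate {on_rate_m_on:.0%} after expressing "
          f"mothers vs {on_rate_m_off:.0%} after silent mothers "
          f"({mem.test} p={mem.p:.2g})")
    print(f"ploidy: modal foci {cmp['modal_count_diploid']:.0f} (diploid) vs "
          f"{cmp['modal_count_tetraploid']:.0f} (tetraploid), ratio "
          f"{cmp['modal_ratio']:.1f}; onset times not earlier in tetraploids "
          f"(p={cmp['onset_comparison'].p:.2f})")


if __name__ == "__main__":
    main()
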