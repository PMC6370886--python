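# blastula

Quantitative 4D image analysis of the earliest zygotic transcription in
cleavage-stage embryos — with a ground-truthed synthetic movie generator
that closes the loop.

## The problem

Before the mid-blastula transition (MBT), zebrafish embryos divide every
10–20 minutes in cycles that alternate S-phase and mitosis with no gap
phases, while the bulk genome stays transcriptionally silent. A small set
of loci (most prominently the *miR430* microRNA cluster) escapes this
repression and fires inside a pair of chromatin-depleted nuclear
compartments, one per set of homologous chromosomes. Live two-channel
movies — a chromatin marker (H2B or PCNA fusion) plus a fluorescent
antisense-oligo label on the nascent transcripts — capture this as paired
bright foci that appear during S-phase, grow to a plateau volume of roughly
16 µm³, and collapse at mitosis, frame after frame across metasynchronous
division waves.

Turning such movies into numbers requires a chain of steps: detect foci and
nuclei, track nuclei through divisions, classify every frame into a
cell-cycle phase from chromatin texture alone, and reduce the result to
per-nucleus expression spans, per-frame expressing fractions,
anaphase-to-anaphase cycle lengths, and compartment volume dynamics. This
package implements that chain as a tested, reusable pipeline — and, because
public 4D datasets of this process are scarce, pairs it with a
synthetic embryo-movie generator that emulates the statistical structure of
the real data and provides exact per-nucleus ground truth for every stage.

## What is inside

| module | role |
| --- | --- |
| `blastula.simconfig` / `lineage` / `render` | synthetic embryo: division tree with per-generation S-phase elongation, metasynchronous wave, S-phase-restricted paired foci, chromatin holes, diploid/tetraploid, triptolide- and chk1-like perturbations; rendered to calibrated two-channel TIFF with truth CSVs |
| `blastula.detection` | band-pass (DoG) spot/nucleus/dark-region detection with a monotone sensitivity contract and threshold-independent half-max size measurement, 2D and 3D |
| `blastula.tracking` | greedy nearest-neighbour linking with division resolution and focus-to-nucleus assignment (stable allele indices) |
| `blastula.cellcycle` | area/SD/entropy chromatin features, rule-based phase calls smoothed onto the legal phase grammar, anaphase-to-anaphase cycle lengths with cycle = S + M exactly |
| `blastula.quantify` | expression records (onset, span, delay from S entry), per-frame expressing fractions, foci counts, volume series with peak and plateau |
| `blastula.stats` | Pearson correlations, rank-sum / t / ANOVA+Tukey comparisons, mother→daughter memory analysis (chi-square with Fisher fallback), ploidy comparison |
| `blastula.pipeline` / `cli` | `run-all` orchestration with a deterministic run directory and provenance manifest; `blastula` console script |
| `analysis/01…06` | numbered narrative drivers reproducing the study's analyses on the default synthetic embryo |

## Worked example

```python
from blastula import SimConfig, simulate_truth, render_movie, \
                     run_pipeline, PipelineConfig

cfg = SimConfig(seed=1)               # 12 founders, two division rounds
truth = simulate_truth(cfg)           # lineage + expression ground truth
movie = render_movie(truth, cfg)      # (59, 2, 20, 200, 200) uint16
result = run_pipeline(movie, PipelineConfig(), out_dir="run")
print(result.stats)
```

Running the numbered drivers (`cd analysis && python 01_simulate_embryo.py`
etc.) on this default embryo prints, among other things:

```
nuclei: 84 across 3 generations; 77 expressing
foci:   recall 1.000  precision 0.996
nuclei: recall 0.998  precision 0.986
phase accuracy 0.933 (0.962 allowing +-1 frame at boundaries)
cycles: 48 measured, 100% within one frame of truth
77 expression records; 96% of onsets in S-phase
span correlations: vs cycle r=0.88, vs S r=0.65, vs M r=0.14 (p=0.37)
chk1: S p=0.0012 (elongated), M p=0.078 (unchanged)
triptolide: cycle p=1 (unchanged), 0 expression records
128_cell: peak 15.1 um^3, plateau 2.5 min
512_cell: peak 17.1 um^3, plateau 7.2 min
ploidy: modal foci 2 (diploid) vs 4 (tetraploid), ratio 2.0
```

Reading these numbers: transcription switches on almost exclusively during
S-phase and its detectable span tracks S-phase (not mitosis) length; cycle
elongation across the 128→512-cell generations is carried entirely by
S-phase; the compartment volume plateaus near 16 µm³ with a longer plateau
at the 512-cell stage; and tetraploid nuclei carry exactly twice the foci
of diploid ones without activating earlier.

## Scope

The package analyses movies (real or synthetic) with one chromatin and one
transcript channel. It does not model photophysics (bleaching, drift),
does not attempt machine-learned segmentation or deconvolution, and makes
no absolute RNA quantification from intensities. See `docs/methods.md` for
the model, parameter and calibration details.
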