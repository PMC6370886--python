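# Methods

## The synthetic embryo

The generator produces the statistical structure of a two-channel
lightsheet movie of the animal pole of a pre-MBT zebrafish blastula. It is
first-class, tested code: every downstream accuracy claim in the test
suite is made against its per-nucleus ground truth.

**Lineage and timing.** `n_founders` nuclei are placed on a jittered grid
inside the field (blastomere nuclei at these stages form a near-monolayer,
so the animal-pole cap is modelled as a flat field; the wave axis is the x
coordinate). Each founder's clock is offset by `x / wave_speed_um_per_s`,
which yields the metasynchronous division wave. Every nucleus draws its
anaphase-to-anaphase cycle length from a per-generation normal
distribution (defaults 10, 13, 17 min with SD 0.8–1.3 min for the
128/256/512-cell-like generations, read qualitatively from published
cleavage-stage timings); M-phase is constant (default 4 min), so S = cycle
− M and all elongation is S-phase elongation. M is divided into
prophase/prometaphase/metaphase/anaphase/telophase at fixed fractions
(default 0.25/0.15/0.2/0.25/0.15). The comparatively long anaphase
fraction guarantees that the ~51 s sampling catches at least one
anaphase-pair frame per division, which is what pins cycle measurements to
frame precision; the fractions are configurable. A chk1-like perturbation
multiplies S by `chk1_s_scale` (default 1.5) and leaves M unchanged; a
triptolide-like perturbation forces all expression off and leaves the
lineage untouched.

Conventions: a nucleus is *born* at the end of its mother's anaphase (the
moment the sister masses are fully separate); its own anaphase interval
still belongs to it, rendered as two masses moving linearly toward the
future daughter positions. Daughters are placed at ±1.2 nuclear radii
along a random division axis (damped toward the border tangent near field
edges) and then relaxed to a minimum spacing of 2.25 radii.

**Expression.** From `onset_generation` on, a nucleus expresses with
probability `p_express` (default 0.75), plus `memory_boost` (default 0.15)
if its mother expressed. Onset is S-phase start plus a uniform fractional
delay (default 5–35% of S length); the detectable span runs to the end of
S (`span_coupling`, default 1.0) with a residual shoulder — volume reduced
to `residual_m_frac` (default 0.3) of the plateau — through
prophase–metaphase, fading to zero at anaphase. Each expressing nucleus
carries one focus site per homolog set (2 or 4 by ploidy) at fixed offsets
in the nuclear mid-plane, at least two hole radii apart. The focus volume
profile rises over `rise_min` (3 min) to `peak_volume_um3` (16 µm³),
plateaus through S, and decays as above. Tetraploid nuclei are 2^(1/3)
larger, matching their doubled DNA content.

**Rendering.** Chromatin: soft-edged ellipsoids whose radius factor,
brightness and internal texture follow the phase (S large/dim/smooth →
prophase shrinking/brightening → compact bright prometaphase/metaphase →
two separating anaphase masses → re-expanding telophase); active focus
sites multiply the chromatin down by up to 90% inside `hole_radius_um`
(1.5 µm), scaled with the focus volume — the chromatin-depleted
transcription body. Transcript channel: near-uniform spheres of the truth
volume. A Gaussian of ~0.4 µm lateral / 0.5 µm axial width stands in for
the optics (no further PSF modelling), followed by scaled-Poisson shot
noise plus Gaussian read noise over a constant background. Defaults
(background 100, read SD 6, photon scale 0.25, signal amplitudes 160–400)
put plateau foci at SNR ≈ 20, chosen so that default detection operates at
but not above ~0.95 recall — a non-trivial regime.

**What the generator does not emulate.** No bleaching, drift, or depth-
dependent attenuation; no cytoplasm/yolk background; nuclei are stationary
between divisions; focus sites do not wander within the nucleus; all foci
of a nucleus share one volume profile. Passing tests therefore demonstrate
that the measurement chain recovers the truth under realistic geometry,
sampling and noise — not that it is robust to every artefact of real
lightsheet data.

## Detection

A difference-of-Gaussians band-pass at the requested feature scale
(surround ratio 1.6 for spots, 3.0 for nuclei); response maxima are
thresholded at `k · σ_resp / (sensitivity_pct / 100)`, where σ_resp is the
robust wavelet noise estimate of the image propagated through the kernel's
L2 norm and k = 5.5 was calibrated once on synthetic fixtures so that 100%
sensitivity sits near 0.95 recall for plateau foci at default noise. Interactive
spot-detection tools do not document their sensitivity mapping; only the monotone
contract (higher % → never fewer detections) is reproducible, and it is
property-tested. Sizes are measured by half-max segmentation of the
lightly smoothed raw image, which makes areas/volumes independent of the
sensitivity setting; merged half-max regions of close spots are split by
nearest-peak (Voronoi) assignment.

Nuclei are segmented by seeded watershed (detection peaks + background
marker), so touching nuclei cannot merge; component counting inside each
mask (chromatin-scale threshold at 45% of the robust intensity range)
yields the two-component anaphase signature, complemented by an in-plane
elongation feature (major/minor axis ratio of the mask, threshold 1.7) for
merged anaphase pairs whose components overlap.

**3D volumes.** Counting half-max voxels on a 1 µm z grid systematically
underestimates a ~1.6 µm-radius blob (the axial PSF erodes the half-max
surface and voxel centres miss the partial end slices). Volumes are
therefore measured on a z-upsampled local box at a 42%-of-peak level, a
constant calibrated once against rendered spheres of known volume under
the package's optics model; with it, recovered plateau volumes are
unbiased to within a few percent.

The shipped parameter presets (`DetectionParams.foci_2d()` etc.: scale
3 px with a 3–75 px area window for foci, 200–3000 px for nuclei,
sensitivity 80–150%, scaled to 5–150 / 750–20 000 voxels in 3D) are the
documented defaults for real lightsheet magnifications; the synthetic
movies use a 25–700 px nucleus window because their 0.5 µm pixels put
metaphase plates below 200 px. Dark (chromatin-hole) detection inverts the
image inside the nucleus mask and scales its threshold from the response
spread *inside* the mask, so chromatin texture does not read as holes;
textured S-phase nuclei need sensitivities near the top of the documented
range (~130%), consistent with the convention of raising sensitivity on noisier data.

## Tracking

Greedy nearest-neighbour linking under `max_step_um` (default 6 µm, about
one nuclear radius) with one-frame gap bridging. A division is recorded
when a tracked nucleus is succeeded by two detections within the division
radius (1.4 × max step); the mother's matched continuation is reinterpreted
as one daughter in that case, and a recent two-component (anaphase)
observation strengthens the candidate. Blastula fields are sparse and
nuclei essentially stationary, so no global optimisation is needed. Foci
are assigned to the track whose mask, dilated by 1 µm, contains their
centroid (rim foci); allele indices stay stable by nearest-previous-site
matching within 2 µm.

## Phase segmentation and cycle measurement

Per-frame features: mask area, intensity SD, Shannon entropy (64 bins over
the frame's intensity range) and component count. Classification uses
relative-area bands normalised to the track's 95th-percentile footprint —
S ≥ 0.88, prophase 0.40–0.88, prometaphase 0.28–0.40, metaphase < 0.28,
with two-component or strongly elongated condensed objects called
anaphase, and a leading condensed run before the first S frame read as
telophase. Band edges were calibrated once on rendered fixtures with known
phases. Relative-area bands were chosen over per-track area/SD quantiles
because quantile thresholds shift with the phase-duration mix inside the
track window (S-phase occupies ~70% of frames), whereas bands normalised
to the S-phase footprint are duration-invariant. The raw labels are then
projected onto the legal cyclic grammar (telophase → S → prophase →
prometaphase → metaphase → anaphase → …) by a minimal-edit dynamic
programme; between consecutive observations the phase may advance two
states when the skipped state is shorter than the frame interval
(prometaphase, metaphase, telophase at default fractions), and
proportionally more across detection gaps.

Cycle length is anaphase-to-anaphase. Both ends of each cycle are placed
on the same sampling convention — the frame at which the daughter masses
first resolve — using, in order of preference: the frame the daughters
appear, an interior mitosis→re-entry boundary of the (unsplit) track, or
the frame after the final sampled anaphase pair. A division whose
completion was never observed (track lost during condensed phases, or the
movie ends first) is right-censored rather than scored with a biased
endpoint. S length is the number of S-labelled frames inside the window,
and M = cycle − S, so cycle = S + M holds exactly at frame quantisation.
On default-noise synthetic movies this recovers ~40–50 cycles per movie
with ≥95% of them within one frame interval of truth.

## Quantification

An expression record needs a run of at least `min_persist_frames` (2)
frames with an assigned focus — single-frame blips are discarded; the span
ends at the last detection, so residual prophase/metaphase signal counts.
When a timeline shows an interior division, focus frames on either side
produce separate per-cycle records. Onset delay is measured from the start
of the S run containing the onset. Volume series are per allele, aligned
to first detection; the plateau is the longest consecutive run within 80%
of the peak (80% is this package's operational plateau definition,
configurable).

## Statistics

Thin wrappers over scipy/statsmodels: Pearson r with the t-transform
p-value, Mann–Whitney U, Welch's t, one-way ANOVA with Tukey HSD for the
multi-stage comparisons, chi-square (Fisher's exact when any expected cell
is below 5; the contingency test for the memory table is this
package's choice) and rank-sum for daughter spans by mother
state. All tests are two-sided; results carry group summaries and are
cross-checked in the test suite against permutation oracles and a
closed-form Pearson computation, with type-I error verified at the nominal
level on null simulations.

## Problem sizes and test design

The default study conditions are a desk-scale crop of the animal pole: 12
founders followed through two division rounds (84 nuclei, ~50 frames,
200×200×20 voxels at 0.5×0.5×1 µm). Power/null repetitions (200 null
runs, 50 perturbation replicates, 100 memory replicates) use truth-level
simulations — lineage and expression assignment without rendering — since
the hypotheses concern the drawn quantities; rendered end-to-end checks
run once per condition on top. The memory power simulation uses a
128-cell-like cohort (16 founders, two cleavages, ~96 daughter pairs),
the scale at which a +0.3 on-probability boost is detectable with ~80%
power; the default crop is smaller than the cohorts tracked in real embryos. The 512-cell volume analysis uses four nuclei over one cycle in
3D. The synthetic default is more synchronous than a real embryo (the
instantaneous expressing fraction peaks near 0.9 rather than ~0.6); wave
speed and per-generation SDs are exposed in the config for stronger
desynchronisation.

## Known limitations

Phase calls distinguish prometaphase from metaphase only through the area
bands, so their boundary is soft; anaphase frames whose masses neither
split nor show two components are occasionally read as metaphase (both are
within one frame of a true boundary). Tracking is greedy: a daughter that
stays merged with a neighbour for two frames can delay its birth frame by
as much. Volume measurements assume blob-like foci under the package's
optics model; the 42% level constant would need recalibration for a
different PSF. The 2D pipeline reports focus areas only; volumes require
the 3D mode, which is intended for small fields.
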