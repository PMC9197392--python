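# Methods

## What the pipeline computes

`cerebellopipe` quantifies how optogenetic stimulation of the cerebellar
dentate nucleus (DN) drives downstream activity in the ventrolateral
(VAL) and centrolateral (CL) thalamus, primary motor cortex (M1) and
dorsolateral striatum (DLS), and how that drive changes after θ-burst
stimulation, across genotypes (wild type vs *Gnal*-haploinsufficient,
"GNAL") and pharmacological states (naive saline, acute oxotremorine,
post-oxotremorine saline). It also computes the behavioral read-outs
used alongside the electrophysiology: footprint gait parameters,
open-field locomotion from video tracking, active-wake percentage, and
the aggregation of ordinal dystonia severity scores.

Because the underlying animal recordings are not required, a
synthetic-data module generates every input with known ground truth, and
the test battery is built around parameter recovery against that truth.

## Evoked-response quantification

For each unit, spikes are binned relative to each stimulation onset into
a peristimulus time histogram (PSTH) with 10 ms bins spanning a 300 ms
pre-onset baseline (30 bins) and the stimulation span (10 bins for the
100 ms probing pulse). Bins are half-open `[left, right)`. Counts are
totals over events; rates are `counts / (n_events × bin_width)`.

* **Evoked rate change** (`evoked_delta_rate`): mean rate over the
  stimulation bins minus mean rate over the baseline bins, in Hz.
* **Responsiveness**: a unit responds when at least one stimulation bin
  exceeds the baseline mean by more than 4 baseline-bin standard
  deviations. The threshold is read as `(bin rate − baseline mean) >
  k × SD(baseline bins)` — a threshold on the raw rate against the SD
  alone would be dimensionally inconsistent whenever the baseline is
  nonzero. The SD is taken across the 30 bins of the event-averaged
  histogram (not across trials), with the sample (n−1) denominator.
  A degenerate zero SD falls back to any stimulation bin exceeding the
  baseline mean. Under the default configuration the criterion's null
  false-positive rate on Poisson units is well below 5% (measured ≈0.3%
  at 20 Hz / 500 events) and decreases monotonically in `k`.
* **Afferent volley**: the earliest, putatively direct response
  component, measured as the baseline-subtracted rate in a 10 ms
  region-specific window after light onset — 0–10 ms in the DN (direct
  ChR2 excitation), 4–14 ms in the thalamus (one synapse), 7–17 ms in
  cortex (two synapses). The protocol leaves the striatal window
  unspecified; it defaults to the cortical 7–17 ms (the cerebello-
  striatal path is also oligosynaptic) and is configurable.
* **Stability check** (`early_late_responses`): the evoked rate change
  computed separately on the first ⌈n/2⌉ and remaining events.
* **Unit classes**: striatal units split at a 6 Hz mean rate into
  slow-spiking (putative projection neurons) and fast-spiking (putative
  interneurons); the tie at exactly 6 Hz counts as fast.
* **Firing regularity**: `cv_isi` = SD/mean of interspike intervals over
  the full provided interval (0 for clock-like firing, ≈1 for Poisson);
  undefined (NaN) below three spikes.

## Stimulation protocols

* Probing: 100 ms pulses at 0.25 Hz (one pulse every 4 s), so the 300 ms
  baseline never overlaps the preceding pulse.
* Plasticity induction: 20 ms pulses at 8.33 Hz in two 40 s trains
  separated by a 2 min pause. Taken literally this yields
  `floor(40 × 8.33) = 333` pulses per train (666 total); protocol
  descriptions sometimes round such schedules to 600 pulses, and the
  generator follows the rate/duration arithmetic rather than the rounded
  total. θ-bursts are modeled as single repeating 20 ms pulses, not
  nested pulse packets.

## Spike generation model

Simulated trains are piecewise-constant-rate Poisson processes: a
homogeneous baseline `b = baseline_rate[region] × state_factor`, plus an
increment `Δ = evoked_delta[region] × genotype_gain × plasticity_gain`
inside `[onset + latency, onset + latency + window)`. Negative
increments (depression) are realized by thinning the baseline inside the
window. Refractoriness is deliberately omitted — the analyses assume
nothing about it, and a baseline CV_isi ≈ 1 is acceptable for the
regularity read-out.

Defaults are simulation choices typical of awake rodent recordings, not
measured values: baseline rates DN 40, VAL 12, CL 10, M1 8, DLS 5 Hz;
evoked increments DN 20, VAL 15, CL 12, M1 10, DLS 6 Hz; response
latencies equal to the volley-window onsets with windows spanning the
rest of the 100 ms pulse. Effect multipliers are likewise a documented
table of simulation choices: genotype gain 1.3 for the mutant (elevated
cerebello-thalamic excitability), state rate factor 0.7 under the
cholinergic agonist (depressed tonic firing), and post/pre θ-burst gain
1.5 for wild types in saline (potentiation), 1.0 for mutants in saline
(absent potentiation), 0.7 for mutants under the agonist (depression).

## Spike sorting

Waveform snippets are mean-centered and projected onto their top three
principal components; units are separated by k-means with 10 restarts
and seeded initialization. When the cluster count is unknown it is the
silhouette-maximizing k in `[2, k_max]`, falling back to k = 1 when the
best silhouette is below 0.3. The floor sits deliberately above the
≈0.22–0.26 silhouette that a k-means split of a *single* isotropic
cluster attains in three PCs, and well below the ≳0.5 of genuinely
separated units; a 0.2 floor would split single units. Both the number
of PCs and the floor are conventional, config-overridable defaults — the
original sorting stage specifies only "k-means on PCA". The stage is
also exposed as a scikit-learn-compatible estimator (`WaveformSorter`)
for use in sklearn pipelines.

The snippet generator builds k templates as a common biphasic shape plus
orthonormal harmonic perturbations scaled by `separation`, giving a
pairwise template distance of `separation × √2` against i.i.d. Gaussian
sample noise.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test, unpaired ones the
Mann–Whitney U test, both two-sided; exact small-sample distributions
are used when there are no ties and n ≤ 25, otherwise the normal
approximation with tie correction. All-zero paired differences return
p = 1 with zero effect. Multi-group comparisons use Kruskal–Wallis
followed by Dunn's pairwise z-tests (pooled-rank formulation with the
standard tie correction) adjusted by the Holm–Šidák step-down method;
adjusted p-values are floored at the raw ones. Factorial comparisons use
a two-way ANOVA with interaction and type-II sums of squares — cell
counts (units per condition) are generally unequal, and type-II is the
conventional choice when the interaction is not the design focus. A
one-way repeated-measures ANOVA is provided as a documented alternative
for re-measured units but is not used by the default comparison path.
Boxplot summaries follow the 1.5 × IQR whisker convention with
linear-interpolation quartiles. Significance stars map p < 0.05 / 0.01 /
0.001.

## Gait metrics

Inputs are ordered, side-labeled hind-print coordinates in cm. The
travel direction is the principal axis of all prints oriented by the net
first-to-last displacement (the walking alley fixes this axis in the
real assay), which makes every metric invariant under rigid rotation and
translation.

* step length = net first-to-last displacement / (n_prints − 1). The
  "distance of travel" is read as net displacement; a path-length
  variant would differ on curved walks.
* sigma = SD of pooled consecutive right–right and left–left distances.
  "Standard variation" is read as the population (n-denominator) SD;
  `ddof=1` is available as an option.
* gait width = mean perpendicular distance of each print to the line
  through its opposite-side preceding and succeeding prints.
* alternation coefficient = mean |0.5 − d(R,L)/d(R,R)| over left prints
  bracketed by consecutive right prints, distances measured as
  projections on the travel axis. The projection convention makes a left
  print midway between its flanking rights score exactly 0.5 regardless
  of lateral width; Euclidean distances would not. The preceding right
  print anchors d(R,L) (the nearest-right alternative is not used).
* linearity = mean absolute change, between consecutive right steps, of
  the angle each subsequent right print makes with the line
  perpendicular to travel through the first right print, in degrees.
* stride length = mean consecutive same-side distance; hind-base width =
  mean distance between temporally adjacent opposite-side prints.

The footprint generator walks a (possibly drifting) heading with
alternating lateral offsets of ±width/2 and rounds the print count up to
an odd number so the first and last prints share a side; with zero noise
every metric then equals the configured geometry exactly (step length L,
sigma 0, gait width w, alternation 0, linearity 0, stride 2L, hind base
√(L² + w²)), which the tests assert to 1e-9.

## Open-field tracking and locomotion

Tracking stages per frame: optional circular ROI masking → grayscale →
binary threshold (default 128; the animal is dark on a light arena
floor) → edge-preserving bilateral filter and Gaussian blur (σ = 1.2 px)
to suppress thin, high-spatial-frequency structure such as the headstage
cable → Canny edge detection (high threshold 0.3, rejecting the
low-amplitude residue of smoothed thin structures) → fill of closed
contours → largest connected region → centroid as the arithmetic mean of
the enclosed pixels (the center of mass of a binary blob). Pixel
positions convert to cm through the single `px_per_cm` scale factor.
Frames with no detectable contour inherit the last valid position; more
than 10% imputed frames raises a hard quality warning, and a fully blank
stack falls back to the frame center rather than fabricating motion.

Speed is frame-to-frame displacement over the frame interval, averaged
in centered 1 s sliding windows (truncated at the session edges); total
distance is the sum of consecutive displacements. The occupancy
histogram covers the arena bounding square (20×20 bins). Thigmotaxis
index = fraction of samples beyond 0.75 of the arena radius; percent
time in center = samples within 0.5 of the radius. These zone radii are
conventional definitions — the assay reports the indices without
formulas — and are config-overridable. Active wake counts samples whose
1 s window speed is at least 1 cm/s, after dissolving bouts shorter than
1 s; threshold and minimum bout are documented defaults for the external
scoring convention the assay cites. Dystonia scores (ordinal 0–4 per
10-min block, several raters) aggregate as per-block across-rater means,
a session mean of block means, and the exact-match inter-rater
agreement fraction.

The trajectory generator is a heading random walk whose per-frame
displacement is exactly `speed × dt`, reflected at 0.95 R and — when a
wall bias is set — at an inner boundary `0.9 R × wall_bias`, so full
bias confines the path to the outer annulus. The video generator renders
a dark disc with sub-pixel area coverage on a light background, with
optional Gaussian pixel noise and a one-pixel cable distractor.

## Orchestrated runs and reproducibility

`run_experiment` simulates every genotype × state × epoch × region cell
(defaults: 40 units per region, 150 probing pulses → 600 s sessions, a
5 min open-field trajectory, three gait trials, six score blocks),
computes per-unit response summaries, runs the paired pre/post, group
and factorial statistics, and writes a report bundle with a manifest
recording the seed, a configuration hash and every analysis constant
used. One root seed governs the run; stage seeds derive from it via
`SeedSequence((root, *stage_indices))`, so identical configuration and
seed give byte-identical outputs while stages stay statistically
independent. Floats are written with 17 significant digits and read back
with round-trip parsing, making tabular round-trips bit-exact.

## Problem sizes in the test battery

The property tests run at the sizes the recovery claims are stated for:
2,000 null and 400 evoked units for criterion calibration (500 events
each), 200 simulations per evoked increment for recovery error, 100
replicate 40-unit pre/post cohorts for plasticity detection (100 pulses
per session), 20 seeds for sorting accuracy, exhaustive sign-pattern
enumeration (n ≤ 8) plus a 1,000-replicate global-null for the
statistics, a 200-frame tracking video at 8 px/cm (a typical camera
resolution for a 38 cm arena), and two full default-size runs for
reproducibility.

## Known limitations

* The Poisson model has no refractoriness, bursting or adaptation, so
  synthetic CV_isi cannot fall much below 1 without changing the model;
  regularity shifts are emulated only through rate changes.
* The tracking fixture is a clean disc; occlusions, shadows, rearing
  postures and non-circular body shapes are not emulated, so passing
  tests bound algorithmic error, not real-video robustness. The cable
  distractor is rejected by the smoothing stages in all but rare frames
  where it touches the blob.
* Gait inputs are coordinates; ink-blot segmentation and foot-angle
  measurement are out of scope.
* Dystonia scoring itself remains a human judgment; only aggregation is
  implemented.
* Thigmotaxis/center radii, the active-wake threshold and the DLS volley
  window are documented assumptions, exposed in configuration rather
  than fixed facts.
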