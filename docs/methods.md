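# Methods

## Scope and model

`nucshift` implements an anchored nucleosome-positioning analysis for
paired-end MNase-seq.  The biological question it serves: when a chromatin
remodeler (e.g. BRG1, the BAF-complex ATPase) is acutely depleted, do the
−1 and +1 nucleosomes flanking transcription start sites, enhancer summits
or TF motifs move *toward* the anchor, narrowing the −1/+1 spacing?  The
pipeline answers this per anchor and classifies each anchor into one of
four patterns: non-shift, Shift 1 (+1 moved upstream), Shift 2 (−1 moved
downstream), Shift 3 (both).

### Occupancy scoring

Fragments are filtered to the canonical mono-nucleosome length range
140–180 bp (bounds inclusive — the natural reading of a stated "range").
Each fragment is reduced to its midpoint, the dyad proxy; for even-length
fragments the midpoint of `[start, end)` is `(start + end − 1) // 2`
(rounds down; the convention is documented and fixed).  The raw
nucleosome center positioning (NCP) score `S_k` is the normalized midpoint
count at base k, and the center-weighted occupancy is

    O_k = Σ_{j=−73..+73} S_{k+j} · w_j,   w_j = exp(−(j/20)² / 2).

The Gaussian weight has σ = 20 bp and half-width 73 bp (one nucleosome
half-length); `w_0 = 1` and `w_±20 = e^{−1/2}` to machine precision.
Scores outside the computed window are treated as zero; anchor profiles
are extracted over an extended window and cropped, so padding never
affects values inside the search region.  Profiles are strand-oriented:
negative offsets are always upstream of the anchor; strandless anchors
(enhancer summits, motifs) are treated as "+"-oriented, i.e. reported by
genomic left/right.

### Peak calling

Local maxima of the smoothed profile are filtered by topographic
prominence with threshold 0.1, computed with `scipy.signal.find_peaks`
(identical semantics to MATLAB `findpeaks`' `MinPeakProminence`): a peak's
prominence is its height minus the higher of the two minimal valleys
separating it from the nearest higher point on each side, window edges
acting as boundaries.  Because a fixed absolute threshold is only
meaningful on a common scale, each profile is rescaled to max 1 within the
±150 bp search window before thresholding; this makes the criterion
depth-independent.  Plateau maxima report their center sample, rounding
toward the anchor.  Among qualifying peaks, the highest in [−150, 0) is
the −1 nucleosome and the highest in (0, +150] is +1 (exact offset 0
belongs to neither); equal heights break toward the anchor, which is
conservative with respect to calling shifts.  Anchors lacking a peak on
either side are "uncallable" and excluded from shift testing.

### Sub-base-pair apex refinement

The positions handed to the shift test are refined by quadratic
(parabolic) interpolation of the three samples around the called apex.
Integer-grid positions quantize the bootstrap distribution — at realistic
depths the positional standard error is about 1 bp, the same size as the
grid — which distorts the tail probabilities of a z statistic.  Apex
interpolation is the standard signal-processing remedy and restores a
continuous sampling distribution; the integer peak grid (and all
prominence logic) is unchanged.  Refinement falls back to the integer
offset at window edges or flat neighborhoods.

### Positional uncertainty and the shift test

The variance of a called position is estimated by a fragment-level
bootstrap: the anchor-window fragments (before the length filter) are
resampled with replacement B = 200 times, and the full filter → profile →
peak-call pipeline is rerun inside the loop; the SE is the standard
deviation of the called position over successful resamples.  Resamples
where the anchor is uncallable are dropped and counted; anchors with
> 50% uncallable resamples are flagged low-confidence and excluded.

Movement between conditions is tested one-tailed toward the anchor at 90%
confidence:

    z = (pos_depleted − pos_control) / sqrt(se_ctrl² + se_dep²),

significant when z exceeds Φ⁻¹(0.90) ≈ 1.2816 in the expected direction
(positive for −1, negative for +1).  Only the toward-anchor direction is
tested, since all defined patterns narrow the spacing; nucleosomes moving
significantly away fall into non-shift.  No multiple-testing correction is
applied across anchors (a fixed per-test confidence level); Benjamini–
Hochberg is available as an option.  Group summaries are per-anchor calls
averaged within each label — the only route that also yields the group
counts — with spacing = (+1 position) − (−1 position) per condition.

### Association

Shift groups are compared with decreased-signal region sets (e.g. reduced
remodeler binding, accessibility, nascent transcription) via a one-sided
hypergeometric test, P(X ≥ k) for overlap k between a set of size K and a
group of size n in a universe of N callable anchors of the relevant kind
(overlap is only defined where both classifications exist).  Cells are
reported as −log10 P.

### Normalization

Three schemes, selectable per experiment:

* **Library size**: CPM, count / library_size × 10⁶.
* **Spike-in chromatin**: factor_i = mean(mouse reads) × spike_i /
  spike_ref, with the reference defaulting to the control library with
  median spike reads (deterministic and robust to outliers).  The factor's
  product form is one faithful reading of a two-component description and
  is isolated behind a single function.  The contract: technical global
  scaling (depth) cancels, genuine global signal changes survive.
* **Conserved genes**: factors from genes with > 500 CPM in *every*
  library (the stricter reading of "robust expression"; configurable) and
  no remodeler peak in the gene body extended 2 kb upstream (matching the
  ≤ 2 kb TSS convention used elsewhere).

Background correction subtracts the outside-peak per-bp read density from
per-peak densities and floors at zero (negative corrected densities have
no physical reading).  Region conventions are fixed: 5′/3′ regions are
TSS/TTS ± 1000 bp; peaks ≤ 2 kb from a TSS are TSS-class, > 5 kb are
nonTSS, intermediate distances belong to neither.  Differential summaries
apply the joint cutoff P < 0.05 and fold-change > 1.3 (1.5 for mRNA-level
comparisons), with the differential statistic itself pluggable — the
p-values and fold changes may come from any upstream test.  Tertile
grouping is by rank with stable tie-breaking; group sizes differ by at
most one.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes, so
every stage is testable without sequencing data:

* positioned −1/+1 nucleosomes with Gaussian dyad jitter ("fuzziness")
  around true centers — Gaussian because it is the minimal fuzziness model
  matching the smoothing kernel's assumptions;
* Poisson per-nucleosome fragment counts and a uniform background rate,
  with background fragments drawing lengths from the same law so the
  canonical filter acts uniformly;
* a truncated-normal fragment-length law (mean 160, SD 20, support
  100–240 bp) placing mass on both sides of the 140–180 bp window;
* condition-specific dyad displacements injected per group in the
  depleted condition, applied to dyad centers (matching the
  midpoint-as-position convention);
* spike-in libraries where a technical global factor scales signal,
  mouse and spike reads together.

Defaults are the study conditions: −1/+1 centers at −95/+55 bp, fuzziness
SD 20 bp, 900 expected fragments per nucleosome plus ~0.2 background
fragments/bp (≈ 2000 fragments per anchor window), 200 anchors per group,
and injected displacements matching the reported TSS magnitudes
(+1 upstream 36 bp; −1 downstream 49 bp; 40/−27 bp for the double shift).
Replicates are i.i.d. redraws under deterministic per-condition,
per-replicate sub-seeds of one master seed; fixed seeds give byte-identical
output.

What the generator does **not** model: sequence (no FASTQ, mappability or
MNase sequence bias), nucleosome arrays beyond the −1/+1 pair,
condition-dependent occupancy or fuzziness changes, and inter-anchor
heterogeneity in architecture.  Passing tests therefore demonstrate the
statistical machinery — calibration, recovery, classification — under the
assumed generative model, not robustness to the full messiness of real
chromatin data.

## Numerical choices and degenerate inputs

* Even-length fragment midpoints round down; plateau peak centers round
  toward the anchor.
* Zero-SE shift tests: equal positions → z = 0, not significant; unequal
  positions → significant by convention with infinite z (logged).
* Hypergeometric tails use the log-stable survival function.
* Corrected densities floor at 0; zero-length peaks, non-positive library
  sizes/factors, inconsistent overlap counts and malformed BED intervals
  are rejected with diagnostics.
* All coordinates are 0-based half-open internally; 1-based only where an
  output format requires it.

## Problem sizes in tests

The test suite and acceptance script run the calibration study at 2000
anchors (≈2000 fragments each, B = 200 bootstrap resamples), the recovery
study at 200 anchors per group, the hypergeometric null at 10⁴ draws and
the spike-in recovery at 20 libraries — sizes chosen so each property is
measured with useful Monte-Carlo precision while a full run stays in the
minutes range on a laptop core.

## Known limitations

* The bootstrap SE treats the anchor's window fragment count as fixed;
  between-replicate biological variability is not modeled (replicates are
  pooled at the fragment level before profiling; per-replicate calling
  remains possible by running conditions separately).
* Per-anchor profiles are computed within windows, not genome-wide; the
  pipeline is anchored by design and produces no de-novo nucleosome map.
* In cohorts where one nucleosome moves close to the anchor, the
  stationary partner's false-call rate runs slightly above nominal
  (tail overlap perturbs its apex), visible in the recovery study's
  per-group label accuracy.
* The built-in differential test is a plain two-sample rank comparison;
  reproducibility-optimized statistics are out of scope and should be
  supplied upstream.
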