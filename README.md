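# nucshift

Nucleosome positioning and −1/+1 shift classification for MNase-seq.

When a chromatin remodeler such as BRG1 (the ATPase of the mammalian
SWI/SNF-like BAF complexes) is acutely depleted, the nucleosomes
immediately flanking transcription start sites and enhancer summits can
slide *toward* the element, narrowing the −1/+1 spacing and compromising
accessibility and transcription.  `nucshift` implements the analysis that
detects and classifies these movements from paired-end MNase-seq
fragments, for people who have anchor sets (TSSs, p300/enhancer summits,
TF motif sites) and fragment files for two conditions and want per-anchor
shift calls, group summaries and region-set associations.

## The method

1. **Occupancy.** Fragments of canonical mono-nucleosome length
   (140–180 bp inclusive) are reduced to their midpoints (dyad proxies).
   The NCP score S_k is the normalized midpoint count at base k; the
   center-weighted occupancy smooths it with a Gaussian weight,

       O_k = Σ_{j=−73}^{+73} S_{k+j} · w_j,   w_j = e^{−(j/20)²/2},

   at single-base resolution, strand-oriented around each anchor.
2. **Calling.** Peaks of the smoothed profile are filtered by topographic
   prominence ≥ 0.1 (profile rescaled to max 1 in the ±150 bp search
   window); the highest qualifying peaks in [−150, 0) and (0, +150] are
   the −1 and +1 nucleosomes.  Positions are refined to sub-base-pair
   apexes by parabolic interpolation, and each position gets a bootstrap
   standard error (B = 200 fragment-level resamples through the full
   pipeline).
3. **Shift testing.** Between control and depleted conditions each
   nucleosome is tested one-tailed toward the anchor at 90% confidence,
   z = Δpos / √(se₁² + se₂²).  Anchors are labeled **Shift 1** (+1 moved
   upstream), **Shift 2** (−1 moved downstream), **Shift 3** (both) or
   **non-shift**; every significant pattern narrows the spacing
   (+1 − (−1)).
4. **Normalization & association.** Library-size (CPM), spike-in
   chromatin and conserved-gene normalization factors; peak background
   correction; fixed region conventions (TSS ≤ 2 kb, nonTSS > 5 kb,
   5′/3′ ± 1 kb); differential summaries at P < 0.05 and fold-change
   > 1.3; one-sided hypergeometric association between shift groups and
   decreased-signal region sets.

A synthetic fragment generator (`nucshift.simulate`) produces cohorts
with known −1/+1 architectures, Gaussian dyad fuzziness, background
fragments, a fragment-length law straddling the canonical window and
injected per-group dyad displacements, so the entire pipeline is testable
without sequencing data.

## Worked example

Simulate a 20-anchor cohort whose −1 nucleosome moves 49 bp downstream on
depletion, call both conditions and summarize:

```python
import nucshift as ns

cfg = ns.SimulationConfig(n_anchors=20, groups={"Shift2": (49.0, 0.0)}, seed=7)
archs, anchors = ns.default_cohort(cfg)
control = ns.simulate_fragments(archs, cfg, "control")
depleted = ns.simulate_fragments(archs, cfg, "depleted")

caller = ns.NucleosomeCaller()
calls = []
for _, anchor in anchors.iterrows():
    wt = caller.call_with_se(control, anchor, "control", B=200, seed=1)
    aid = caller.call_with_se(depleted, anchor, "depleted", B=200, seed=2)
    calls.append(ns.shift_call(wt, aid))

summary = ns.summarize_groups(calls)
print(summary[["label", "n", "minus1_ctrl", "minus1_dep", "shift_minus1",
               "spacing_ctrl", "spacing_dep"]].round(1).to_string(index=False))
```

```
    label  n  minus1_ctrl  minus1_dep  shift_minus1  spacing_ctrl  spacing_dep
non-shift  0          NaN         NaN           NaN           NaN          NaN
   Shift1  0          NaN         NaN           NaN           NaN          NaN
   Shift2 18        -95.2       -45.5          49.6         150.0        100.4
   Shift3  2        -94.9       -45.1          49.7         151.2         98.8
```

18 of 20 anchors are correctly labeled Shift 2 with the injected 49 bp
downstream movement of the −1 nucleosome recovered to within 1 bp
(−95.2 → −45.5) and the −1/+1 spacing narrowed from 150 to 100 bp; the two
misclassified anchors picked up a chance significant +1 call (the
one-tailed test runs at a 10% per-nucleosome false-call rate by design).

The same pipeline is scriptable from the shell:

```sh
nucshift simulate --seed 7 --out sim/
nucshift callnuc --fragments sim/fragments_control_rep0.bed \
    --anchors sim/anchors.bed --condition control --out calls_wt.tsv
nucshift callnuc --fragments sim/fragments_depleted_rep0.bed \
    --anchors sim/anchors.bed --condition depleted --out calls_aid.tsv
nucshift shift --control calls_wt.tsv --depleted calls_aid.tsv \
    --out shifts.tsv --summary-out summary.tsv
```

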