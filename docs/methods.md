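# Methods

## Data model and conventions

All coordinates are 0-based half-open in transcript space; GFF3's
1-based closed intervals are converted at the file boundary, DNA input
is uppercased and T→U. The substrate of every analysis is a
`StopCountProfile`: per-transcript integer arrays of RT-stop counts and
read coverage for one condition and replicate.

**Stop-position convention.** Reverse transcriptase extends the cDNA
toward the template 5′ end; a read whose 5′-most aligned base maps to
position *i* implies termination at the neighbouring template
nucleotide, so the stop is assigned to *i − 1* (reads starting at 0 go
to a run-off bucket). The convention is arbitrary in isolation — what
matters is that the simulator and the extractor share it, which they
do: a simulated stall at a folded region's 3′-terminal G corresponds to
reads starting one base past the region.

**Replicate merging** is a position-wise sum, not a mean, so count-scale
thresholds downstream (≥ 50 reads/nt, Li⁺ coverage > 60) are interpreted
on the merged scale. Pairwise Pearson correlation of log-transformed
per-transcript stop totals is reported and a value below the floor
(default 0.9) warns without failing; on small or signal-free simulations
totals are noise-dominated and the warning fires benignly.

## Synthetic-data generator

The generator emulates exactly what the two assays are designed to see,
with truth labels:

* Transcripts (default 50, lengths 400–800 nt) carry at most one planted
  motif each, drawn from the six subclasses (uniform mix by default),
  placed ≥ 60 nt from the ends. The 50 nt flanking a plant are drawn
  from {A, C, U}, so no unplanned grammar match can arise near a planted
  region and truth recovery by the classifier is exact. Loop-length
  constraints keep each plant out of every stricter grammar (a G2L1-4
  plant always has a loop of 3–4 nt, a G2L1-9 plant one of 5–9 nt, and
  G3 plants contain too few G₃ tracts for the classes above them).
* rG4-seq: under K⁺ or K⁺/PDS, a `stall_efficiency` fraction (default
  0.9) of RT events crossing a folded region's 3′ end terminate at its
  last base — coverage 5′ of that base scales by 1 − 0.9 and the stalled
  events' stops land on the base. A background stop rate of 0.02 per
  covering read applies everywhere. Li⁺ is drop-free.
* SHALiPE: expected stop counts are `base_coverage` (default 100)
  everywhere; in states where a region is folded (in vitro K⁺ always,
  in vivo per the truth flag) the 3′-most G of each tract carries
  `lastG_enrichment` × that rate (default 8). In vitro Li⁺ is uniform by
  construction.
* Counts are negative binomial with size parameter `noise_dispersion`
  (default 20; Poisson in the infinite limit), matching the
  overdispersion of sequencing stop counts. All outputs are
  deterministic functions of the seed; replicate and condition streams
  are independent children of it.

No quantitative stall efficiency or probe enrichment factor is
measurable from published figures, so 0.9 and 8× are calibration
choices: strong enough that a folded region is unambiguous at the
default coverage, weak enough that the noise model matters. Genic
regions are a fixed 20/60/20 split into 5′UTR/CDS/3′UTR — the genic
localization analysis needs only a coarse three-way label.

What the generator does **not** emulate: read-level artefacts (ligation
and PCR bias, alignment error), transcript-abundance variation,
non-uniform background reactivity, partial or heterogeneous folding
states, and natural sequence composition (flanks are sanitized and the
background is uniform-random). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
stated generative model, not performance on real libraries.

## RTS detection

For each candidate base the local drop is
d = log₂((mean coverage in the 10-nt 5′ window + 1) / (mean coverage in
the 10-nt 3′ window + 1)), computed per replicate. The windows are named
for transcript orientation; since the enzyme travels 3′→5′, a stall
makes d negative. A linear model d ~ condition is fitted across the
replicates of both conditions and the F test on the condition term
(equivalently one-way ANOVA; the implementation is a vectorized
`f_oneway`, cross-checked in the tests against `statsmodels` OLS +
`anova_lm`) gives the p-value. Bases with p < 0.05 whose drop is more
negative in the stabilizing channel are emitted; the test is two-sided
with the orientation filter applied afterwards, and no multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists but
is off, matching the published raw-p procedure — the motif gate
downstream absorbs the resulting false calls). Bases are only tested
where the control channel's 3′ window averages ≥ 20 reads/nt, a guard
against vacuous log-ratios at uncovered positions.

Adjacent significant bases within 5 nt collapse to one representative:
the base with the most negative condition contrast, ties broken by
smaller p. The contrast localizes the stall sharply — the p-value
plateaus over ~±5 nt around it — and with this rule ≥ 90% of simulated
stalls are recovered within ±2 nt at default signal strength.

## Motif grammar

Subclass patterns are regular expressions over {G, N, H} with N = any
base and H = any base but G, tried in a fixed priority order (canonical
G₃ first, loosest G₂ last); the first subclass matching anywhere in the
query window wins, which makes the assignment hierarchy sound by
construction. The bulged class allows a single non-G inside either
middle tract (GGHG or GHGG). Within the winning subclass the match whose
3′ end lies furthest 3′ is chosen, since the stall marks the quadruplex
3′ end. G-tracts are reported as maximal G-runs within the match; extra
guanines beyond the minimum tract width are absorbed by the N loops.

The classification window is the 50 nt ending at the called stall base,
extended 3 nt past it: stall localization is only a couple of
nucleotides accurate, and without the slack a site called one base
inside the final tract truncates the motif.

Transcriptome-wide prediction uses the permissive grammar G≥2, loops
1–15, four tracts, scanned non-greedily (shortest match at each feasible
start, found by dynamic programming over (position, tracts remaining))
and non-overlappingly (scanning resumes after each match), so intervals
are disjoint and reproduce a brute-force minimal-match enumerator
exactly. Predicted regions with mean merged Li⁺ coverage above 60, no
overlap with any detected region, and full 50-nt flanks form the
"undetected" pool. Genic localization uses the midpoint rule: the label
is the feature containing the region midpoint, including for regions
crossing a feature boundary; "spanning" is reserved for a midpoint
covered by no feature and "unknown" for unannotated transcripts.

## Structure competition

Per-nucleotide base-pairing probability is the sum of partition-function
pair probabilities over all partners, clipped to 1. The folding engine
is injected: the ViennaRNA bindings (partition function, dangling-ends
model 2, 22 °C) when available, synthetic stubs otherwise — the
partition-function marginal is used rather than any single-structure
annotation, since a minimum-free-energy structure has no per-nucleotide
probability. Each region's guanines are split positionally into 8
near-equal-occupancy bins (regions with fewer than 8 Gs leave some bins
empty; empty bins are missing, never zero) and each 100-nt flank into
20 five-nt bins counted from the region edge outward, 15 flagged for
display. Bin means are occupancy-weighted sums pooled over regions, so
half-sets concatenate to the joint result. A paired two-sided t test
compares per-region mean-G BPP with mean-flank BPP; with fewer than two
regions the bins are returned without a test, and a zero-variance
difference vector short-circuits to t = 0, p = 1 (or p = 0 for a
constant non-zero difference).

On uniformly random synthetic sequence, G-runs pair *more* than their
flanks (abundant C and U partners via G:C and G:U wobble), the opposite
of the depletion expected over quadruplex guanines in natural
transcripts; the tested machinery is the binning and the paired
contrast, not the sign of the effect.

## Gini and folding score

The Gini index is the literal double sum over selected residues,
implemented in the equivalent sorted O(n log n) form
Σᵢⱼ|rᵢ−rⱼ| = 2 Σₖ (2k+1−n) r₍ₖ₎, which the tests hold to within 1e-12 of
the O(n²) definition on 1,000 random vectors. Selections: tract Gs
(guanines in runs of ≥ 2; the headline statistic), non-tract Gs
(singleton guanines) and non-G bases as negative controls. All-zero
selections are reported as missing (the mean in the denominator
vanishes); selections with fewer than two residues are errors.

Regions are scored on merged counts when Gini(K⁺) ≥ 1.1 · Gini(Li⁺)
(multiplicative form, so a zero Li⁺ Gini with positive K⁺ Gini — an
infinite ratio — passes) and tract guanines average ≥ 50 reads/nt in
all three states; the published filter does not name a state, so the
strictest reading is the default and both thresholds are configurable.
Non-passing regions are retained with their filter flags and no score.
Landscape summaries report the median score, the count and fraction
above 0, and per-subclass / per-genic-region comparisons by one-way
ANOVA with Tukey HSD, excluding groups of fewer than two regions.

## Problem sizes

The bundled analyses and checks run at desk scale: 50 transcripts / 40
planted regions for the demo, 60 signal-free transcripts (~28,000
tested bases) for caller calibration, 100 planted stalls for
sensitivity, 200 regions for folding-score recovery, and 1,000 random
200-nt sequences for predictor/enumerator agreement — sizes at which
every stochastic check is stable across seeds while the full suite runs
in well under a minute of compute per module.

## Known limitations

* The linear-model stall test assumes independent replicates and
  roughly homoscedastic log-ratio noise; extreme coverage imbalance
  between channels is only partially absorbed by the pseudocount.
* Raw p < 0.05 without correction means site-level false calls scale
  with transcriptome size; region-level conclusions should always pass
  through the motif gate and the SHALiPE filters.
* The folding score is a ratio of noisy Gini differences: regions whose
  in vitro anchors are close (ratio filter barely passed) have
  high-variance scores, and values outside [0, 1] are expected.
* G4-aware or pseudoknot folding is out of scope for the structure
  module; the partition function treats G-tracts as ordinary sequence.
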