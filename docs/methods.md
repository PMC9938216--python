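# Methods

This note documents the models and procedures implemented in `silamnet`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions.

## Z-ratio quantification (`silamnet.quant`)

The input is a long-format table of protein × replicate light/heavy ratio
measurements (¹⁴N sample over ¹⁵N internal standard) with a per-entry
peptide-fit quality r² and a genotype label per replicate.  The chain is:

1. **Quality filter.** Entries with r² ≤ 0.5 are dropped (strict
   inequality).  An empty result warns rather than errors, since the caller
   may be probing a subset.
2. **Aggregation.** Multiple peptide-level rows per (protein, replicate)
   collapse to their median ratio.  The median is robust to the residual
   outliers the next step targets.
3. **Grubbs filter.** Per protein, across its replicate values (on the
   log2 scale when log transformation is on), the single most extreme value
   is removed iteratively while G = max|x−x̄|/s exceeds the two-sided
   critical value at α = 0.01, using the classical t-based form
   G_crit = (n−1)/√n · √(t²/(n−2+t²)) with t the (1−α/2n) quantile of
   t(n−2).  The test needs n ≥ 3; smaller groups pass through flagged.
   A zero SD leaves data untouched (G undefined ⇒ nothing is extreme).
4. **Coverage filter.** Proteins quantified in fewer than 3 samples of
   either genotype are dropped, so both genotype averages rest on at least
   three observations.
5. **Per-replicate standardization.** Z(P,i) = (P_i − Mean_i)/SD_i with
   Mean_i and SD_i computed over the proteins quantified in replicate i.
   Sample SD (n−1) is used; the choice only rescales each column jointly
   and is configurable.  By default ratios are log2-transformed first:
   isotope-ratio distributions are multiplicative, and standardizing the
   log compresses the heavy right tail.  Both conventions are exposed
   because the upstream convention is not observable from the data.
6. **Z-ratio.** Per protein, Z-scores are averaged within genotype over the
   replicates in which the protein was quantified; the DUP − WT difference
   is divided by the sample SD of that difference across all proteins.
   The denominator is shared by every protein — it is an empirical scale
   for the whole experiment, not a per-protein error.  Fewer than two
   proteins, or zero spread (all differences identical), make the scale
   undefined and raise an error.
7. **Calls.** Strictly above +1.96 ⇒ up, strictly below −1.96 ⇒ down,
   otherwise null.  1.96 is the two-sided 5% normal quantile; exact ties
   are null.

Because the final scale is the empirical SD of Z-differences, the null
fraction flagged is self-calibrating: with no planted effect roughly 3–6%
of proteins exceed |1.96| (the Z-differences are approximately normal but
the empirical-SD scaling keeps the tail fraction below the naive 5%), and
with a 1 log2-unit effect at 0.2 noise the planted proteins separate with
ROC AUC > 0.99.

## Gene-set profiling and interactome calling (`silamnet.enrich`)

All lists are first intersected with the declared background universe —
for membrane proteomics, the set of proteins detectable in membrane
fractions — so that detectability cannot masquerade as disease
association.  Over-representation uses the hypergeometric upper tail
P(X ≥ k) including the observed overlap (the standard over-representation
convention); a two-sided variant (doubled smaller tail, capped at 1) is
available because some published profiles report it.  Results carry the
chance expectation nK/N, fold over chance, and percent enrichment.
Benjamini–Hochberg adjustment is applied within each direction's family of
sets, mirroring per-panel reporting.

Interactome calling compares bait and IgG-control spectral counts (≥ 2
replicates each): mean(bait) ≥ 2 × mean(IgG) and a one-tailed Welch t-test
p < 0.1.  Welch is used because equal variances are not defensible for
counts this small; the variant is configurable.  A zero IgG mean passes
the fold criterion whenever the bait mean is positive — proteins absent
from the control are biologically the strongest candidates — and is
flagged `not_in_control` rather than given an infinite fold.  When both
arms are constant the t statistic is undefined and the call falls back to
comparing means (p set to 0 or 1).

Cross-dataset comparison reports the overlap of two hit lists over a
shared universe with its enrichment, plus Pearson r/R²/p of paired effect
sizes when supplied (skipped below 3 overlapping genes).  An exclusion
list removes, e.g., genes inside the duplicated locus itself, whose cis
dosage effects would correlate trivially.

## Subnetworks and hubs (`silamnet.netmod`)

Subnetworks are induced subgraphs of seed proteins over a
physical-interaction edge database supplied as a file (SIF or TSV).  The
expansion offered is deliberately simple — up to k highest-degree database
neighbors — because association-weighted expansion belongs to external
services and the downstream statistics only need the resulting graph.
Bait pulldown edges merge on top with per-edge provenance tags
(`database` / `iap`) unioned on duplicates, so merging never creates
parallel edges and never decreases an existing degree.  Gene symbols are
uppercased for matching: seed lists are human, proteins mouse, and case is
the only systematic difference.

Betweenness is the exact Brandes accumulation (via networkx) normalized by
(n−1)(n−2)/2, which puts a star center at exactly 1; unreachable pairs in
disconnected graphs contribute 0.  Ranks break ties lexicographically so
output is deterministic.  Hub prediction tests each locus gene's brain
co-expression set for over-representation of subnetwork proteins and
attaches constraint (pLI), disease-flag and proteome Z-ratio annotations
verbatim — the evidence is combined qualitatively, so no composite score
is computed.

## Trace analytics (`silamnet.imaging`)

ΔF/F₀ uses a running-median baseline (default 30 s window, nearest-edge
padding); the median tracks slow drift while ignoring sparse transients.
Slice recordings get one extra pass with a fixed 5-tap symmetric
(Hann-derived) FIR kernel: the original smoothing filter for that modality
is not specified precisely enough to reproduce, so the kernel is pinned
here for reproducibility rather than configurable per run.

Peaks are local maxima with prominence ≥ the modality default (0.15
culture, 0.20 slice, 0.01 glutamate sensor); amplitude is the ΔF/F₀ value
at the peak and half-width the width at half-prominence.  On isolated
noise-free template transients the detector recovers amplitude and
half-width to well within 1% provided the sampling rate resolves the
half-width; at 2 frames/s the half-frame interpolation of the
instantaneous rise adds ~0.25 s to the measured width, which is a sampling
limit, not an implementation error.

The co-activation null redistributes each ROI's peak frames uniformly at
random (count-preserving, without replacement) in each of 1000
permutations — the weakest-assumption null; circular shifting, which
preserves within-ROI intervals, is available as a config alternative.
Frame-wise co-active counts are pooled over all frames × permutations and
the threshold is the ceiling of the 99.9th percentile (per-permutation-max
pooling available).  Because co-active counts are small integers, the
ceiling typically lands on the percentile's own atom and the fraction of
chance frames at or above threshold is bounded near 0.1–0.5% rather than
exactly 0.1%; consequently the spurious-event rate is only small relative
to recordings with a realistic number of genuine network events (the
defaults below).  Network events are maximal contiguous supra-threshold
runs with no gap bridging; their size counts distinct ROIs peaking inside
the run.

Pairwise correlation is Pearson R on the continuous ΔF/F₀ traces (the
raster-based variant can be had by correlating the raster rows); constant
traces are excluded with a flag.  Pairwise delay takes, for each event of
one ROI, the nearest event of the other within ±2.1 s and averages |Δt|
per pair; pairs with no in-window matches are excluded from the summary.
Synchrony-split partitions population-trace peaks at 0.2 ΔF/F₀ with
exact-boundary values assigned to the low class (strict > for high).

Evoked responses are normalized to the mean of the first 50 pre-stimulus
frames; amplitude is the post-stimulus maximum of F/F₀ − 1, AUC the
trapezoidal area, and T₁/₂ = ln2/k from a one-phase exponential fit
(A·e^(−kt) + C) to the post-peak segment.  Non-convergent or non-decaying
fits flag T₁/₂ as missing while amplitude and AUC are still returned.

## Seizure and behavior statistics (`silamnet.sevstats`)

The two-sided Fisher p sums the hypergeometric probabilities of all tables
with the observed margins whose probability does not exceed the observed
one (with a 1e-7 relative tolerance for floating-point ties, as in common
statistical packages); this reproduces, from the reconstructed 14/17 vs
7/16 incidence table, the published p = 0.0324.  Kaplan–Meier curves and
the log-rank test are delegated to lifelines; animals without the endpoint
are censored at the 7200-s observation end, never excluded.  Racine scores
are ordinal, so severity uses median/IQR and an exact Mann–Whitney test;
no parametric test is offered for scores.  The latency-shift metric
averages per-trial ratios of mean latencies over trials where both
genotypes reached the endpoint.  Routine omnibus machinery (ANOVA,
post-hoc corrections) is left to standard packages.

## Synthetic data (`silamnet.syndata`)

Generators are pure functions of a validated `SynthConfig`; identical
configs give byte-identical output, and per-ROI/per-genotype RNG
sub-streams are keyed by index so enlarging a dimension does not reshuffle
earlier draws.  Ground truth is always returned alongside the data, never
embedded in it.

Defaults emulate the study conditions the pipeline targets:

- **Quant tables**: 1000 proteins, 5 + 5 replicates, N(0, 0.2) log2 noise,
  5% up / 5% down at ±1 log2 unit planted in the DUP arm only, 1% gross
  outliers (3–6 log2 units), 5% missing cells (missing completely at
  random — the simplest mechanism the coverage filter must handle), and
  r² ~ Beta(8, 2) so ~5% of entries fail the quality filter.
- **Gene universes**: 4000 genes, disjoint sets of 100, query of 200.  The
  planted set's overlap with the query is drawn from Fisher's noncentral
  hypergeometric distribution with the odds parameter solved numerically
  so the expected overlap equals fold × chance; fold = 1 reduces exactly
  to the central hypergeometric null.  Only the designated leading set(s)
  are planted; the rest are null competitors.
- **Graphs**: Barabási–Albert base (n = 100, m = 2) for a scale-free-ish
  degree profile.  The hub is planted on the highest-degree base node and
  then strengthened with extra edges, so the truth label is the degree
  maximum by construction — a uniformly random plant would frequently
  lose to the base graph's own hubs and make recovery claims vacuous.
- **Traces**: 150 ROIs at 2 frames/s for 10 min.  Transients are
  instantaneous-rise exponential-decay bumps with decay constant
  τ = halfwidth/ln2 so the full width at half maximum equals the
  configured 1 s; amplitude 0.5 ΔF/F₀.  Network events at 0.02 Hz
  (≈ 1.2/min, typical of mature cultured cortical networks) recruit 60%
  of ROIs with N(0, 0.2 s) onset jitter; independent per-ROI transients
  at 0.02 Hz; baseline 1.0 with a ±2% slow sinusoidal drift and
  N(0, 0.03) ΔF/F₀ sensor noise.  Note the two noise scales: quant-table
  noise (0.2 log2 units) and trace noise (0.03 ΔF/F₀) parameterize
  different measurement processes and are separate fields.
- **Cohorts**: 16 WT / 17 DUP animals, GTCS probabilities 0.44 / 0.82,
  Weibull(shape 2) onset latencies (smooth monotone hazard; nothing in the
  assay pins the shape) truncated at the 7200-s window, Racine 6–7 for
  GTCS animals (death probability 0.5 given GTCS) and 1–5 otherwise.
- **Spectral counts**: Poisson counts, 3 + 3 replicates; true interactors
  at bait mean 10 with IgG mean ≤ bait/4 (20% absent from IgG entirely),
  background at equal means 2.

What the generators do **not** emulate: raw spectra or chromatograms,
pixel-level microscopy (ROI segmentation is upstream of this package),
correlated missingness or batch structure in proteomics, bursty or
oscillatory background firing, photobleaching, and genotype differences in
trace dynamics.  Passing recovery tests therefore demonstrates that the
analysis chain is correct and calibrated under its stated assumptions, not
that those assumptions hold in any particular recording.

## Problem sizes and tolerances

The validation suite runs at desk scale: exhaustive oracle sweeps cover
all hypergeometric configurations with N ≤ 20 and all 2×2 tables with
N ≤ 12; betweenness is checked against path enumeration on 100 random
graphs of ≤ 8 nodes; recovery and calibration claims use 3–20 seeds at the
default generator sizes.  Dataset-level magnitudes of the original study
(thousands of dysregulated proteins, the 100-node epilepsy subnetwork and
its hub statistics, a Z-ratio of 115.6 for the top protein) require the
full experimental inputs and external interaction/co-expression databases;
they serve as reference values in documentation and are deliberately not
regression targets.  Published significance figures are reproduced where
the printed inputs determine them (the incidence table's p = 0.0324, the
1.9-fold interactome enrichment); the printed interactome p-value itself
(8.56 × 10⁻²⁶) is not exactly recoverable from the printed counts under
either tail convention and is treated as reference only.

## Known limitations

- The Grubbs filter assumes approximate normality per protein across
  replicates; with n = 5–10 its power is limited and only gross outliers
  are removed.
- The co-activation threshold inherits the discreteness of small counts
  (see above); comparisons across recordings should use identical ROI
  counts and durations.
- The permutation null treats peaks as exchangeable across time;
  recordings with strong slow nonstationarity would need the circular
  scheme or a windowed null.
- Exponential-decay fits assume a single kinetic component; biphasic
  decays will converge to an average rate.
- Symbol-based matching cannot resolve paralogs or species-specific
  naming beyond case.
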