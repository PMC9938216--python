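# silamnet

Analysis toolkit for a multi-level study of the 16p11.2 duplication mouse
model of neuropsychiatric disease: SILAM (stable isotope labeling in
mammals) quantitative membrane proteomics, disease gene-set profiling,
protein–protein interaction subnetwork and hub analysis, Ca²⁺/glutamate
fluorescence network-synchrony analytics, and seizure/behavior statistics.
Every stage is paired with a synthetic-data generator that plants known
ground truth, so the whole chain is testable end to end without the raw
experimental data.

## Who it is for

Researchers post-processing protein-level ¹⁴N/¹⁵N ratio tables, profiling
hit lists against curated disease gene sets, ranking hubs in seeded
interaction subnetworks, analyzing ROI × frame fluorescence recordings of
neuronal cultures or slices, or comparing chemoconvulsant seizure cohorts —
and anyone who wants a reference implementation of these analyses with
planted-truth validation.

## The statistics at the core

**Z-ratio quantification.** Within each biological replicate *i*, protein
values are standardized over the proteins quantified in that replicate,

    Z(P,i) = (P_i − Mean_i) / SD_i,

and the between-genotype effect per protein is

    Zratio_p = ( Z̄(p,dup) − Z̄(p,wt) ) / SD[ Z_diff(p1…pn) ],

where the denominator is the standard deviation, over all quantified
proteins, of the difference of genotype-averaged Z-scores.  Proteins with
Zratio > 1.96 (< −1.96) are called up- (down-) regulated.  Upstream
filters: peptide-fit quality r² > 0.5 (strict), iterative two-sided Grubbs
outlier removal at α = 0.01 per protein, and a coverage filter requiring
quantification in ≥ 3 samples of each genotype.

**Gene-set profiling.** Over-representation of a query list (size *n*) in a
set (size *K*) over a declared background universe (size *N*) uses the
hypergeometric upper tail P(X ≥ k), with fold = k/(nK/N), percent
enrichment = (fold − 1)·100, and Benjamini–Hochberg adjustment per
direction.  Bait interactors are called from spectral counts at mean fold
≥ 2 over the IgG control with a one-tailed Welch t-test p < 0.1.

**Subnetwork hubs.** Disease subnetworks are induced subgraphs of seed
proteins over a physical-interaction edge database, optionally merged with
bait pulldown (IAP-MS) edges; hubs are ranked by degree D and exact
betweenness centrality C_B normalized by (n−1)(n−2)/2.

**Network synchrony.** Traces are normalized to ΔF/F₀ against a
running-median baseline; transients are prominence-detected peaks
(15% culture / 20% slice / 1% glutamate-sensor defaults).  The minimal
co-active ROI count that exceeds chance is the ceiling of the 99.9th
percentile of frame-wise co-active counts pooled over 1000 count-preserving
permutations of each ROI's peaks; contiguous supra-threshold epochs are
network events.  Synchrony is also summarized by pairwise Pearson R and by
mean nearest-event delays within ±2.1 s, and depolarization-evoked
responses by amplitude, AUC and the decay half-life T₁/₂ = ln2/k from a
one-phase exponential fit.

**Seizure statistics.** Incidence by two-sided Fisher exact test
(sum-of-small-probabilities rule), onset/survival by Kaplan–Meier curves
and the log-rank test with censoring at the 2-h observation end, severity
by median/IQR of the ordinal modified Racine score (1–7, 7 = death) with an
exact rank test, sociability by the discrimination index
DI(%) = (t_mouse − t_object)/(t_mouse + t_object)·100.

## Worked example

Simulate a quantification table with planted dysregulation (1000 proteins,
5 + 5 replicates, 5% up / 5% down at 1 log2 unit), run the Z-ratio chain,
then simulate and analyze a seizure cohort:

```
$ silamnet simulate quant --seed 1 --out sim
$ silamnet quantify --in sim/quant_table.csv --out results.csv
47 up, 50 down, 894 null (of 991)

$ silamnet simulate cohort --seed 1 --out sim
$ silamnet stats seizure --in sim/cohort.csv --out report
{
  "genotypes": ["DUP", "WT"],
  "gtcs_incidence": {"DUP": 0.8235, "WT": 0.3125},
  "fisher_p": 0.0049,
  "odds_ratio": 10.27,
  "logrank_chi2": 11.14,
  "logrank_p": 0.00084,
  "severity_p": 0.0097
}
```

The quantification run recovers 47 of the 50 planted upregulated and all 50
planted downregulated proteins among 991 that survive the filters
(`results.csv` has one row per protein with its genotype-averaged Z-scores,
Z-ratio and call).  The cohort report shows the duplication genotype with
~82% generalized tonic-clonic seizure incidence against ~31% in wild-type
littermates (exact p = 0.005), faster onset (log-rank p = 0.0008) and
higher 1-h severity scores (rank-sum p = 0.01) — the same statistical
readouts used on real cohorts.

Python API mirrors the CLI: `silamnet.gen_quant_table`,
`silamnet.quantify`, `silamnet.hypergeom_enrich`, `silamnet.centrality`,
`silamnet.mc_coactivity_threshold`, `silamnet.fisher_2x2`, …

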