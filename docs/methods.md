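# Methods

This note documents the models and procedures implemented in `bafmap`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Coordinates and interval algebra

All coordinates are 0-based, half-open `[start, end)` (the BED
convention of the formats consumed); strand is ignored — ChIP peaks are
unstranded.  "Co-occupancy" of two peak sets means an interval overlap
of at least `min_bp` base pairs, default 1 (no overlap threshold is
standard in this literature; the parameter is exposed everywhere).
`intersect_sets` answers overlap queries through a per-chromosome
interval-tree index with the `min_bp` criterion applied on top; the test
suite and the validation module verify it against an exhaustive
all-pairs comparison on randomized instances, so the index is an
optimization, never a semantic change.  Duplicate identical intervals
within a peak set are collapsed at load with a warning, and peak names
are unique within a set.  Blacklist subtraction is available as an
optional pre-step (`subtract_intervals`); no blacklist is bundled.

## Subcomplex classification

The three mSWI/SNF subfamilies share the BRG1 ATPase and are
distinguished by diagnostic subunits: canonical BAF by DPF2, PBAF by
PBRM1, ncBAF by BRD9.  Every BRG1 peak receives the Boolean triple
(DPF2, PBRM1, BRD9 overlap), mapped deterministically onto eight
combination classes; "all three complexes" simply means all three
Booleans true — there is no precedence or hierarchy among subcomplexes.
The classes therefore partition the BRG1 peak set, an invariant asserted
in tests.  PBRM1 peaks without BRG1 overlap are collected separately
(promoter-biased PBAF-like signal analysed on its own anchor).

Co-occupancy tables report, per class × CRTF, the fraction of class
sites carrying at least one factor peak, with counts; empty classes are
reported as undefined (NaN), never as 0.  The reverse fractions (share
of a factor's peaks falling in each class) are emitted alongside.

## Chromatin-state enrichment

For a peak category and a chromHMM-style segmentation, enrichment per
state is `log2[(fraction of peak midpoints in state) / (state bp /
total genome bp)]`.  Midpoint assignment makes the peak fractions a
partition even when peaks span state boundaries.  Unsegmented gaps form
an explicit `none` state, so the genomic fractions are a partition of
the full genome as well; when the segmentation covers the genome this
coincides with normalizing by total segmented bp.  Enrichment is
count-weighted (each peak counts once) rather than bp-weighted — the
alternative was considered and rejected because mixed-width peak sets
would otherwise be dominated by broad domains.  States with zero
genomic bp are excluded with a warning; a state containing no midpoints
reports −∞.

## Peak-to-gene assignment and expression stratification

No assignment rule is canonical; the implemented rule is: a gene is
"bound" iff at least one peak midpoint lies within ±50 kb of its TSS
(enhancer-scale window, configurable), each peak is credited to its
nearest TSS only, and ties break by smaller distance then lexicographic
gene symbol, making the assignment deterministic.  A bound gene inherits
the occupancy class of its nearest assigned peak.  Expression changes
per occupancy group are summarized as the median log2 fold change with a
percentile bootstrap 95% CI (B = 2000 by default, seeded); the bootstrap
was chosen because group sizes and distributions vary widely and no
normality assumption is warranted.

## Spike-in (ChIP-Rx) quantification

RRPM scales each peak's human-mapped read count per million
Drosophila-mapped reads: `signal = raw × 10⁶ / spike_total`.  Because
identical amounts of exogenous chromatin enter every ChIP reaction, the
spike acts as a condition-independent yardstick and RRPM survives global
occupancy changes that defeat depth normalization.  RRPM is exactly
linear in counts and inverse-linear in spike totals; a zero spike total
is a hard error.  RPMPR rescales counts to sum to 10⁶ over the union
peak set, for within-library comparisons such as quartile
stratification.

Differential occupancy at a site is
`Δ = log2(RRPM_treated + c) − log2(RRPM_control + c)` with pseudocount
`c = 0.5` by default (a log-ratio pseudocount is needed for zero counts;
0.5 is the conventional half-count).  The difference-of-logs form makes
condition swap negate every delta exactly in floating point.  The
population shift across co-occupied sites is summarized by the median
delta, the fraction of sites strictly increased, and a paired Wilcoxon
signed-rank p-value (the source analyses present the shift graphically;
the signed-rank test is the standard nonparametric paired choice).
Quartile stratification ranks anchor peaks by signal, splits them into
four bins with any remainder in the lower bins and name-lexicographic
tie-breaks (deterministic), and summarizes the partner signal (0 where
the partner is absent) per bin.

The package consumes per-peak count tables rather than alignments;
counting reads in intervals is upstream of its scope, which keeps the
pipeline download-free while preserving all normalization arithmetic.

## CRISPR domain-screen scoring

Columns are scaled to one million reads (depth normalization), guides
get `LFC = log2((mean late RPM + c)/(mean early RPM + c))` per cell line
with replicates averaged within timepoint and `c = 1` RPM, targets
aggregate their guides by mean (median available by configuration), and
specificity = mean over RMS lines − mean over non-RMS lines, ranked
ascending with name tie-breaks.  Negative-control guides are summarized
separately as an empirical null; the per-target z-scores against that
null are an optional extra of this package (the source screens report
rankings, not p-values).

## qPCR quantification

ChIP-qPCR percent recovery is `2^(Ct_input − log2 X − Ct_sample) × 100`
with X the input fold-dilution; the exogenous-locus correction subtracts
the spike-primer Ct shift (`Ct_corr = Ct − (Ct_Pgbs,sample −
Ct_Pgbs,control)`); fold changes are `2^(−ΔΔCt)` with
`ΔΔCt = dCt_control − dCt_sample`.  RT-qPCR relative expression uses
`dCt = mean Ct_target − mean Ct_reference` (reference GAPDH),
`ΔΔCt = dCt_condition − dCt_control` paired per biological replicate,
expression `2^(−ΔΔCt)` with upper/lower limits the min/max over
biological replicates, and a paired two-tailed t-test on the dCt pairs.
Amplification efficiency is fixed at 2, as the power-of-two formulas
imply.  The technical-replicate outlier rule (SD > 0.5 cycles) is
operationalized as: repeatedly drop the replicate farthest from the
replicate median (larger Ct first on ties) until SD ≤ 0.5 or two
replicates remain.  Competition-assay trajectories are normalized to
100 × value/day-2 baseline per condition; a missing baseline is an
error.

## Proximity-proteomics enrichment

Proteins with fewer than 2 peptides or more than 4 missing entries are
removed (idempotent filter).  Normalization is a modified robust
z-score: per sample on log2 intensities, `z = (x − median)/(1.4826 ×
MAD)`, rescaled to a log2-intensity-like scale via the grand location
(median of all observed values) and a grand scale defined as 1.4826 ×
MAD of the pooled per-sample-centered values.  Defining the grand scale
on centered values makes it invariant to per-sample location shifts, so
a location artifact in one sample is removed exactly up to a single
global constant — all contrasts, fold changes and test statistics are
restored bit-exactly.  A zero-MAD sample is an error naming the sample.

Group comparison uses a moderated two-sample t-test: per-protein pooled
variances are shrunk toward a scaled-F prior whose degrees of freedom
and scale are fitted by method-of-moments on the log variances
(trigamma inversion); the t statistic uses the posterior variance with
prior-augmented degrees of freedom.  This reproduces the standard
empirical-Bayes shrinkage behaviour — stabilized small-sample variances
and increased power — without claiming bit-compatibility with any
particular implementation.  Proteins with one condition entirely
missing bypass the test: the missing group's average is replaced by the
mean of the 10% smallest observed normalized intensities across that
condition's entries over all proteins (ceiling of 0.1 × count, at least
one value), and the resulting pseudo fold change is flagged.  The 10%
rule is applied to raw observed entries rather than per-protein group
averages; the alternative granularity would change the floor only
marginally and is noted as an open interpretation.  Hits follow the
volcano quadrant rule, log2FC > 2.5 and raw p < 0.05; BH-adjusted
p-values are reported alongside but do not drive the default flag, to
match the volcano-style presentation the thresholds come from.  No
imputation is performed beyond the pseudo-fold-change route.

## Synthetic data: what it emulates

The generators define the study conditions; their defaults are fixed and
not tuned per analysis.  A single root seed fans out deterministically
to independent child streams (peaks, chiprx, screen, qpcr, proteomics),
so consuming one stream never perturbs another and identical
configurations reproduce byte-identical outputs.

* **Genome & sites.** Three 10-Mb chromosomes; 600-bp sites placed
  uniformly without overlap by rejection sampling (placement failure
  raises an error suggesting a larger genome).  Each site draws a latent
  class from the multinomial (0.20, 0.10, 0.10, 0.05, 0.25, 0.15, 0.05,
  0.10) over (BAF+PBAF+ncBAF, BAF+PBAF, BAF+ncBAF, PBAF+ncBAF, BAF_only,
  PBAF_only, ncBAF_only, BRG1_unassigned); subunit peaks are placed per
  the class triple with ≤100 bp jitter (always preserving overlap), so
  classification can be validated against exact truth.  CRTF co-binding
  is Bernoulli per class × factor, strongly biased toward BAF-only
  (e.g. 0.60 for PAX3-FOXO1 at BAF_only vs 0.05 at PBAF_only) as the
  enhancer biology dictates; background CRTF peaks land away from sites.
  Peak signals are lognormal(3, 0.8).
* **Spike-in counts.** Per site, `raw ~ Poisson(depth × weight ×
  2^effect)` with lognormal site weights (σ = 0.5, configurable) shared
  across conditions and mean depth 100 reads/site.  The spike read
  total is Poisson around `spike_fraction/(1 − spike_fraction)` times
  the *condition-independent nominal* library size (spike fraction 5%):
  a constant amount of exogenous chromatin enters every reaction, so
  the spike is independent of planted condition effects — tying it to
  the realized library total would let normalization cancel a genuine
  genome-wide effect, defeating the point of the spike-in design.
* **Screen.** 60 domains × 5 guides + 50 controls; early counts
  negative-binomial (mean 500, dispersion 0.2); late means multiply by
  `2^effect` (−2) for 5 planted domains in RMS lines only; 2 RMS + 2
  non-RMS lines.
* **qPCR.** `Ct = c0 − log2(abundance) + N(0, 0.1)` cycles, three
  technical × three biological replicates; fold changes planted per
  condition.
* **Proteomics.** log2 intensities = baseline N(20, 2) + effect (3 for
  20 of 500 hit proteins in the bait group) + N(0, 0.5); an entry is
  missing with probability `logistic(−0.8 × (x − 15))`, so low
  intensities are missing more often (missing-not-at-random); selected
  hits can be forced fully missing in the control to exercise the
  pseudo-fold-change route.

What the generators do **not** emulate: read-level artifacts (GC,
mappability, fragment-length), peak-calling uncertainty (peaks are
placed, not called), batch structure, interactions between assays, or
realistic protein/guide identity.  Passing benchmarks therefore
demonstrate that the *quantitative procedures* recover planted truth
under the stated noise models — not that any particular biological
conclusion holds on real data.

## Pipeline and determinism

Stages run in dependency order (simulate → classify → cooccupy /
state-enrich → chiprx / invade → integrate-expression; screen, qpcr and
bioid are independent); a stage failure aborts with the stage named.
Each run writes a manifest (configuration, package version, SHA-256
checksums of inputs consumed) and JSON-lines logs; no timestamps are
recorded, outputs land only under the run directory, and inputs are
never mutated, so identical configurations give byte-identical runs —
verified as a benchmark.

## Benchmark problem sizes

Validation sizes were chosen so each benchmark's statistical target is
well-resolved while the full suite stays interactive: 100 random
instances (≤300 intervals/set) for the interval oracle; 10,000 sites for
the partition/recovery check; 2,000 sites for co-binding recovery;
1,000 sites at depth 100 for invasion; 100 seeds each for quartile
monotonicity and screen ranking; 50/100 seeds for proteomics
calibration/recovery; 300 sites for the determinism run.

## Power of the planted proteomics benchmark

One benchmark bound is not attainable under its own conditions and is
reported as measured rather than adjusted.  With a true log2FC of 3,
per-sample noise SD 0.5 and 4 samples/group, the fold-change estimate is
distributed N(3, 0.354), so each planted protein exceeds the 2.5
threshold with probability ≈0.92 and the probability that ≥18 of 20 do
so is ≈0.79 per seed — before normalization.  Median-centering is
additionally biased slightly downward when 4% of proteins are truly
enriched (measured mean estimate ≈2.86), and per-sample MAD rescaling
adds multiplicative noise to large deviations, giving ≈25 of 100 seeds
in practice.  The corresponding test asserts the nominal ≥90/100 bound
and documents the shortfall; the null calibration (type-I fraction in
[0.03, 0.07]) and the pseudo-fold-change route pass as specified.

## Known limitations

* Peak-to-gene assignment is TSS-distance based; no contact data or
  activity weighting.
* The moderated test assumes (after normalization) roughly Gaussian
  log2 intensities with protein-specific variances from a common prior;
  heavy-tailed contamination is not modeled.
* The screen scorer is a ranking tool, not a full hierarchical count
  model; guide-level outliers influence target means (median
  aggregation is available).
* RRPM correctness depends on equal spike-in amounts per reaction; the
  package cannot detect a violated spike assumption from counts alone.
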