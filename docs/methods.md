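# Methods

## Enumeration analytics

The unit of analysis is a patient record with two nonnegative integer CTC
counts (unicapture, quadcapture) and a diagnosis label (NSCLC or SCLC).
Positivity at cutoff *c* is `count >= c`; the study's cutoffs of interest are
1 and 2. Detection rates are computed within a diagnosis stratum; an empty
stratum is an error rather than a silent 0/0. The concordance rate pools both
diagnoses: with 10 + 10 patients those are the only denominators under which
the printed 60% and 85% are integer ratios (12/20, 17/20). All rates are
reported as `positives/total` pairs so the fraction is exact.

The paired comparison of the two methods' counts is a two-sided Wilcoxon
signed-rank test. Zero-difference pairs are dropped before ranking
(Wilcoxon's original treatment), and tied absolute differences receive mean
ranks. With at most 25 informative pairs the exact null distribution of the
positive-rank sum is built by dynamic programming over doubled-rank integer
units (mean ranks are multiples of ½), and the two-sided p-value is
`min(1, 2·min(P(W+ ≤ w), P(W+ ≥ w)))`; beyond 25 pairs the normal
approximation from scipy is used. CTC counts are heavy-tailed over four
orders of magnitude, which is why a rank-based paired test is the appropriate
default. When every pair ties, the comparison is degenerate: p is reported as
1.0 with an explicit flag and a warning rather than an error, so batch
pipelines keep running.

Counts are analysed exactly as recorded; no volume renormalisation between
the enumeration table and the design rule's per-7.5 mL definition is
attempted, and the two modules are independent.

## Single-stage binomial design

The decision rule "promising if ≥ k of n samples are positive" has exact
operating characteristics given by upper binomial tails, computed by direct
summation of exact terms with log-space accumulation (`gammaln` +
`logsumexp`); this is stable for any n and reproduces the study sizing
(n = 20, k = 2, p_null = 0.01, p_alt = 0.20 → power 0.930825, type I error
0.016856) to machine precision. Reporting convention: power to the nearest
whole percent, type I error to one decimal percent. The threshold search
scans k upward and returns n + 1 when no k meets the type-I-error target, so
infeasible designs are flagged rather than silently clamped. A seeded
Monte-Carlo estimator (binomial draws, 3-standard-error agreement) serves as
an independent cross-check in the tests and acceptance script.

## QC floor, ranking and quantile scores

Counts ≤ 2 are treated as below the platform detection threshold and removed
*per data point* (the gene×sample cell becomes MISSING; dimensions are
unchanged). Each sample's retained counts are then ranked descending with
mean ranks on ties. Ranks are invariant to any monotone per-sample transform,
so vendor normalisation and batch effects drop out; no separate
normalisation step is implemented, deliberately.

Samples retain different gene numbers G_s after QC, so raw ranks are not
comparable across samples. The quantile score `(G_s − rank)/(G_s − 1)` maps
rank 1 to 1 and the last retained rank to 0 (a lone retained gene scores 1 by
convention); MISSING scores 0, consistent with plotting below-threshold genes
as zero. A fully-masked sample cannot be ranked and raises an error naming
the sample.

## Selection criteria

"Higher than average" in criterion A is interpreted gene-wise: the comparison
baseline m(g) is the mean of gene g's quantile scores over **all** samples of
the assay (tumor + control, MISSING as 0), and the criterion demands a score
strictly above m(g) in ≥ ⌈0.75·n_tumor⌉ tumor samples and strictly below it
in ≥ ⌈0.75·n_control⌉ controls (14 of 18 and 3 of 4 at the study sizes;
ceilings, per "no less than 75%"). The alternative reading — comparison to a
per-sample average — would measure within-sample prominence, which criteria
B and C already capture; the baseline is nonetheless a single pluggable
function if a different convention is wanted. A gene with identical scores
everywhere can never pass (strict inequalities).

Criteria B and C use top-k membership on fractional ranks (`rank ≤ k`);
MISSING never counts as top-k. Boundaries are inclusive: exactly 5 tumor
top-20 hits and exactly 1 control hit satisfies C. Criteria are evaluated per
assay on separate matrices and combined by counting distinct
(assay, criterion) pairs, with inclusion at ≥ 2 — so A+B+C in plasma alone
qualifies, as does B in both assays.

## Clustering and networks

Heatmap-style clustering uses Euclidean distance and complete linkage, with
MISSING entries set to 0 first. The agglomeration is the naive O(n³)
algorithm with a fixed tie-break (smallest lexicographic pair of cluster
indices), making the merge list fully deterministic under relabeling; scipy's
implementation is used as a cross-check oracle in the tests, not as the
implementation, because its tie behaviour is unspecified. Complete linkage is
monotone; nondecreasing merge heights are asserted on every run. Dendrograms
export as scipy-style linkage matrices, merge-list frames and Newick strings
(branch length = parent height − child height).

Edge filtering keeps confidence ≥ threshold (inclusive, matching the
"minimum required interaction score" convention); 0.700 and 0.900 are
provided as named constants. Components come from networkx over the retained
edges plus any isolated universe genes. Pathway overlap is exact
case-sensitive set intersection.

The packaged pathway and interaction tables are synthetic stand-ins (named
`*_synthetic.tsv`): the alpha-granule membership carries exactly the five
documented members (CLU, SPARC, SRGN, PF4, TGFB1), the rest is illustrative.
They exercise the machinery; they are not database snapshots.

## Synthetic panel generator

The generator emulates a fixed 770-gene digital-count panel over 18 tumor and
4 control samples:

* **Gene baseline means** are log-normal around `baseline_mean` (default 50
  counts) with log-scale spread `gene_mean_sigma` (default 1.5, a ~3-decade
  dynamic range). This is the load-bearing realism choice: because every
  sample shares the same gene means, the top ranks of tumor *and* control
  samples are dominated by the same high-expression genes, so criteria B and
  C have the low background false-positive rate they have on real panels. With
  i.i.d. noise instead, top-10 membership would be lottery noise and
  criterion B would fire on ~20% of background genes.
* **Counts** are negative binomial with variance μ + φμ² (dispersion φ,
  default 0.1, typical of digital counting with moderate biological spread).
* **Low-count component:** a `low_count_mass` fraction of background genes
  (default 0.15) is drawn Poisson(0.5), so the ≤2 QC floor removes a
  substantial set of data points, as it does on real plasma cfRNA panels.
* **Planting.** Criterion-A genes sit at the panel median mean and have tumor
  means multiplied by `effect_multiplier` (default 8). B genes are placed
  above the current column maximum in one tumor sample (round robin) and
  clamped out of every control's top 10; C genes are placed above the maximum
  in five tumor samples and in exactly one control — which exercises the
  ≤1-control allowance and keeps planted C genes from also trivially
  satisfying B. Placements are verified against the default QC floor and
  top-10/top-20 thresholds after generation; a configuration too degenerate
  to honour them raises instead of mislabelling ground truth.
* Identical (config, seed) pairs reproduce matrices bit-for-bit
  (`numpy.random.default_rng`).

Recovery bounds used in the tests were frozen from a calibration of 100
replicates (seeds 0–99) at the default configuration with 10 planted genes
per criterion: sensitivity was 1.0 for every criterion on every seed, and
background false-positive rates peaked at 0.5% (A), 1.5% (B) and 1.2% (C).
The tests therefore require per-seed sensitivity ≥ 0.9 and FPR ≤ 0.03.

What the generator does **not** emulate: gene–gene correlation structure,
sample-quality gradients, probe-level background/hybridization artifacts, or
any relationship between plasma RNA yield and counts (per-sample yield exists
only as cosmetic metadata in the study and drives no computation here).
Passing recovery tests therefore show the selection rules implement their
definitions and separate planted signal from independent-noise background —
not that the criteria would achieve the same operating characteristics on
correlated real panels.

The enumeration simulator draws each (patient, method) count as zero with
probability 1 − positivity_prob, else a log-normal magnitude (default
median e³ ≈ 20, σ = 2, spanning the observed 1–4007 range) rounded to an
integer ≥ 1. Default positivity probabilities are the study's observed rates
(NSCLC 0.4/0.2, SCLC 0.6/0.8 for uni/quad). Methods are drawn independently;
the simulator targets marginal rates, not the inter-method correlation of
real patients.

## Problem sizes

The test suite and acceptance script run at the study's native sizes: the
20-patient table, 10⁶ Monte-Carlo draws for the design cross-check, 200
random toy matrices for criterion oracle equivalence, 100 random matrices
(n ≤ 8) for linkage oracle equivalence, and 100 simulated 770×22 panels for
recovery; the acceptance script summarises recovery over 20 panels.

## Known limitations

* The study's raw NanoString data were never deposited, so the actual
  41-gene plasma list and the published gene identities are not reproducible;
  selection correctness is established by oracle equivalence and planted-gene
  recovery instead.
* The paired-test p-value for the SCLC stratum depends on the (unstated)
  test used in the original analysis; this package's exact signed-rank result
  (p ≈ 0.41) is reported but the published 0.37 is not asserted.
* Two rows of the packaged patient table have a typographically ambiguous
  split between the two methods' counts; the adopted split is recorded in
  `datasets.py` and does not affect any positivity-based statistic.
* Edge/pathway fixtures are synthetic; analyses over them demonstrate the
  machinery, not database-backed biology.
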