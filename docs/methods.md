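# Methods

`agpms` re-implements, as a tested library, the statistical analyses used to
characterize how diet (corn vs wheat) and in-feed antibiotic growth
promotants (AGPs) reshape the broiler-chicken gut microbiome, its
metatranscriptome, and the serum metabolome. The study design it targets is
a 2 (diet) x 2 (AGP) factorial sampled at 10, 24 and 40 days of age, with
distinct birds sacrificed at each age (no longitudinal correlation) and six
gastrointestinal sites.

## Community structure

**Alpha diversity** is the Shannon index, H = -sum p_i log2 p_i, over each
sample's relative abundances (log base 2 by default; the base used by the
original QIIME runs is not recorded anywhere, so it is a parameter).
**Rarefaction** subsamples each sample without replacement to a fixed depth
(default 219 reads, the smallest library in the study) via the multivariate
hypergeometric; shallower samples are dropped with a warning.

**Weighted UniFrac** between two samples is sum_i b_i |p_A(i) - p_B(i)| over
branches i with length b_i, where p(i) is the fraction of a sample's counts
on leaves below the branch. The default is the raw (unnormalized) variant,
which is a metric; `normalized=True` divides by the abundance-weighted
root-to-leaf depth sum, scaling into [0, 1] but losing the triangle
inequality. Both match scikit-bio on random instances (cross-checked in the
test suite); the implementation here is a single postorder pass so that the
branch bookkeeping is explicit.

**PERMANOVA** is the adonis-style sequential (Type-I) decomposition: the
Gower-centered matrix G = -0.5 J D^2 J is projected onto nested design
matrices built in the user-given term order, so "diet accounting for AGPs"
means listing `agp` before `diet`. Pseudo-F uses the full-model residual.
p-values permute sample labels with p = (b+1)/(m+1), so the smallest
achievable p is 1/(m+1). With non-Euclidean distances G has negative
eigenvalues and a term's sequential sum of squares can be slightly negative
(as in vegan's adonis); such terms report F < 0 and p = 1. **PERMDISP**
embeds the distance matrix by principal coordinates (negative eigenvalues
dropped with a warning), computes each sample's Euclidean distance to its
group centroid, and permutes group labels against those fixed distances
(Anderson's procedure). When all distances are zero the F is undefined and
p = 1 is reported with a warning.

## Differential abundance and expression

Counts are normalized by **poscounts** size factors: each feature's
reference is the geometric mean over the samples where it is positive, each
sample's factor is the median of count/reference over its positive features,
and factors are rescaled to geometric mean one. This follows the contract
spelled out for this package; DESeq2's `type="poscounts"` divides the
log-sum by the total number of samples instead, so factors differ slightly —
exact DESeq2 numerics are explicitly a non-goal (no dispersion or
fold-change moderation anywhere).

Abundance filters reproduce the study's rules: OTUs below 0.005% of the
grand total are removed; for the LRT on genes, features need at least 5
counts in at least 4 samples; transcripts with fewer than 5 total reads are
dropped. All thresholds are keyword arguments.

The **NB2 GLM** (variance mu + alpha mu^2, log link, log-size-factor offset)
is fitted by IRLS. The dispersion alpha is estimated per feature by
maximizing the Cox-Reid-adjusted profile likelihood (the adjustment
-0.5 log det(X'WX) compensates for the estimated mean parameters, whose
omission biases alpha low at n ~ 24 and makes downstream tests liberal); the
one-dimensional optimization is alternated with IRLS refits, holding mu
fixed inside each line search — full profiling (refitting beta for every
candidate alpha) was measured to overfit the mean and collapse alpha to zero
on a nontrivial fraction of features, so the fixed-mu approximation is
deliberate. alpha is floored at 1e-8, IRLS runs at most 100 iterations with
convergence at max |delta beta| < 1e-8, and non-converged fits are returned
flagged rather than discarded.

**Likelihood-ratio tests** follow the study's three contrasts per feature:
diet main (diet + agp vs agp), AGP main (diet + agp vs diet), interaction
(diet * agp vs diet + agp), with the dispersion estimated under the full
model and shared with the reduced one. The statistic divided by its df is
referred to an F(df, n - p_full) distribution rather than the asymptotic
chi-squared. This is the one deliberate departure from the obvious
"standard GLM practice" default: with alpha estimated from 24 samples the
chi-squared reference is measurably liberal in the far tail (rejection 0.010
at nominal 0.005 in calibration simulations), which propagates into BH-FDR
above 0.10 in the planted-effect recovery benchmark; the F reference is
calibrated at every threshold we measured (0.049/0.009/0.005 at nominal
0.05/0.01/0.005) and costs nothing asymptotically. `reference="chi2"`
restores the asymptotic behaviour. BH adjustment is always applied within
one explicitly declared family (one term, one contrast) — never inferred.

**Pairwise contrasts** are NB Wald tests on a two-group design. A transcript
is significant when q < 0.05 and |log2FC| > 1 (the study's rule); OTU mode
drops the fold-change gate. Features that are all-zero on one side get a
fold change from pseudocounted (0.5) group means and p = 1.

## Differential co-occurrence networks

Genus-collapsed, poscounts-normalized abundances are filtered by central
tendency: keep genera whose median strictly exceeds the 30th percentile of
all genus medians (strict, reproducing the direction of the study's 86 -> 30
reduction; the exact count is data-dependent and not asserted). Spearman
correlations are computed within each treatment group — exact permutation
null for n <= 8 without ties (cached enumeration; the t-approximation takes
over beyond that, a pragmatic cut-off since the exact null at n = 10 needs
3.6M permutations), edges kept at p < 0.05. Differential correlation between
two groups uses Fisher z: z_diff = (atanh r1 - atanh r2) / sqrt(1/(n1-3) +
1/(n2-3)), two-sided normal p, BH over all pairs, significant at q < 0.05.
|rho| = 1 is clamped to 1 - 1e-6 with a warning. At very small group sizes
(n = 4) clamped perfect correlations make z_diff explode; this is inherent
to the Fisher transform, not special-cased.

## Enzyme and pathway analysis

Per enzyme (EC number), expression of all mapped transcripts is pooled
(a transcript with several ECs contributes fully to each), averaged over a
condition's samples, and log2-transformed with pseudocount 1 (zero handling
is not specified by the upstream tools, so the pseudocount is a parameter).
Taxon shares are fractions of the pooled untransformed expression, by
default at family level. An enzyme is called differentially expressed as
soon as one of its transcripts is (up / down / both / ns) — a deliberately
sensitive propagation rule. Pathway enrichment is the upper-tail
hypergeometric P(X >= k) over gene sets with at least two members in the
universe, BH-adjusted; the universe defaults to distinct enzymes (the
alternative transcript universe is a parameter, since the upstream wording
is ambiguous). Enzyme rarefaction subsamples integer reads without
replacement and reports mean distinct-EC richness per depth.

## Pathway attribution

For a pathway, a treatment comparison and each genus, three log2 fold
changes are computed: (1) pathway-specific — the mean over the genus's
pathway genes of log2((mean_a + 1)/(mean_b + 1)); (2) global RNA — the log2
ratio of the genus's summed expression; (3) 16S abundance — the log2 ratio
of mean genus relative abundance (pseudocount 1e-6 on the relative scale).
Deviations are |pathway - reference|. Genera absent from 16S are excluded
from abundance-referenced comparisons only (the resolution gap the original
analysis also reports). The summary is the fraction of genera deviating by
more than 1 log2 unit (twofold) and a one-sided one-sample Wilcoxon
signed-rank test of median deviation > 2; the two constants are independent
parameters because the upstream description uses both numbers, and the
signed-rank null is enumerated exactly for n <= 12 (valid under ties).
Note the two references are not independent: pathway transcripts are part of
total RNA, so a planted pathway-only shift of +2 produces a deviation from
the global-RNA reference somewhat below 2 (still above 1 in the planted
scenarios tested).

## Interaction-network projection

Homology hits (BLAST outfmt 6 plus percent-overlap and subject-length
columns) are filtered by the study's dual rule — (length > 100 AND bitscore
> 60) OR (identity > 85 AND overlap > 65) — with strict comparisons, so
boundary values fail; one best hit per query survives (bitscore, then
identity, then lexicographic subject id). Whether "overlap" means query or
subject coverage is undefined upstream; the filter just consumes the column.
Node mass is summed mapped expression under a condition, zero-mass nodes are
retained, taxon shares mirror the enzyme profiles, and per-taxon subnetworks
partition node masses exactly.

## AMR rank shifts

Every (gene, sample) expression value is ranked once on the pooled scale
(rank 1 = highest value anywhere, average ranks for ties), then summarized
per condition by each gene's mean rank; `scheme="per_sample"` offers the
within-sample alternative. The shift (control minus AGP mean rank, positive
= higher ranking under AGP) is tested with a paired t-test over genes — the
literal reading of the study's "two-sample paired t-test" on gene ranks. A
constant nonzero shift has zero variance; p = 0 is reported with a
zero-variance flag rather than NaN.

## Metabolomics

PQN divides each sample by the median of its metabolite-wise quotients
against a reference sample; this removes a scalar dilution exactly whenever
more than half the metabolites are unchanged. The study normalized control
and AGP sera against different reference samples (D10-13 and D40-18);
`age_pattern_analysis` therefore runs PQN per treatment arm with
configurable references. Autoscaling standardizes each metabolite to mean 0,
SD 1 (constants become zeros with a warning). Age-pattern correlation is
Spearman rho against the ordinal codes 1-2-3 for days 10/24/40; the
significance rule defaults to raw p < 0.05 (the pattern-matching tool's
convention; BH optional, since the exact rule behind the study's counts is
unstated). The permutation factorial ANOVA computes per-term F statistics
from projection-based sums of squares (sequential = marginal in the balanced
designs generated here) and permutes the response across samples with a
fixed permutation count (default 10,000) instead of the original tool's
adaptive stopping, for reproducibility; BH within each term across
metabolites.

## The synthetic world

Generators are pure functions of (design, seed), split into independent
substreams so the 16S and metatranscriptome arms share one taxonomy and
tree. Defaults: 2 birds per diet x AGP x age cell (24 samples per site),
200 taxa, 5 transcripts per taxon, NB dispersion 0.1, library sizes uniform
on [5000, 20000], planted |log2FC| = 2 in 10% of taxa per main effect and 5%
for the interaction (disjoint sets, random signs), lognormal baseline
abundances (sigma 1.5). The metatranscriptome plants pathway-specific
regulation decoupled from abundance: flagged (genus, pathway) pairs shift
only their pathway-mapped transcripts under AGP, with at least one
pathway-annotated transcript guaranteed per flagged genus. The metabolome
(139 metabolites by default) gives a configurable fraction monotone age
trends in control arms only, with lognormal noise and per-sample dilution.
Homology hits are planted to pass exactly one filter branch (true homologs)
or to fail both (decoys).

What the generators do **not** emulate: compositional closure (counts are
independent NB draws, not multinomial), phylogenetic signal in the planted
effects (the tree is random relative to effect assignment), within-bird
correlation across sites, sequencing-depth-dependent dispersion trends, and
annotation error. A green test therefore establishes that the statistics
recover the planted structure under the model's own assumptions, not that
the pipeline is robust to real-data artifacts outside them.

## Numerical choices and limitations

- BH adjustment caps at 1 and uses a stable mergesort so ties keep input
  order; families are always explicit.
- Permutation p-values are (b+1)/(m+1), never 0.
- Spearman ties get average ranks everywhere.
- PCA scores come from an SVD of the (optionally centered/scaled) sample
  matrix; constant matrices return zero scores with a warning.
- The NB machinery trusts the chi-squared/F machinery only through the
  acceptance calibrations actually run in `tests/test_acceptance.py`; no
  claims are made at sample sizes far from those tested.
- Spec-scale counts (e.g. "86 genera filter to 30") are data-dependent and
  not asserted; only the rules are.
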