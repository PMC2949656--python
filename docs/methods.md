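# Methods and design notes

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that matter for
reproducibility.

## Probe filtering

Probes enter the unsupervised analysis through three sequential
criteria applied to the log2 expression matrix:

1. **Intensity.** Control probes (annotation flag) and probes whose 90th
   percentile of log2 intensity falls below 10 are removed. Percentiles
   use linear interpolation between order statistics throughout the
   package (both here and for the rCV window); this is the dominant
   convention and is recorded in the filter report.
2. **Variance test.** For probe P over n samples, the statistic
   `(n-1) * Var(P) / Varmed` is referred to the chi-square distribution
   with n-1 degrees of freedom, where `Var` is the unbiased (n-1
   denominator) sample variance — the denominator that makes the null
   distribution exact — and `Varmed` is the median variance over all
   probes surviving the intensity step, computed before any selection.
   The test is one-sided (upper tail) by default: the companion rCV
   criterion demands *high* variability, so the selection intent is
   high-variance probes; a `two_sided` flag is available.
3. **Robust CV.** Order the probe's values, remove exactly one instance
   of the minimum and one of the maximum (also under ties), and take
   SD/mean of the remainder. Kept probes must satisfy
   `q95(rCV) < rCV < 10`, with the 95th percentile computed over the
   same intensity-filtered probe universe. A trimmed mean of zero makes
   the rCV undefined; such probes are flagged and excluded. The cap 10
   is interpreted on the plain ratio scale (not percent CV) and is
   configurable.

Because the lower rCV bound is a *cohort percentile*, the set of probes
selected depends on the composition of the whole matrix: the same probe
can pass in one cohort and fail in another with more high-variance
probes. The filter report preserves every intermediate quantity
(variance, statistic, p, rCV, kept flag, failure reason) and the count
chain is checked to be monotone non-increasing.

## Ward clustering on 1 - Pearson

Dissimilarity is `1 - r` (Pearson) between samples or genes; Ward's
linkage is implemented as the Lance–Williams recurrence applied to the
dissimilarity **as given**:

```
d(k, i+j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)] / (n_i+n_j+n_k)
```

This is the historical default of the era's clustering tools (R's
`ward.D`), hence the most faithful dialect for correlation-based
dissimilarities; the squared-input variant (`ward.D2`, what scipy's
`linkage(method="ward")` computes) is available via `squared=True`. The
implementation was cross-checked against R's `hclust(method="ward.D")`
and against an independent error-sum-of-squares recomputation (the test
suite's oracle). Merge ties break at the lowest pair index, making runs
bit-reproducible. Heights are non-decreasing (Ward is reducible); the
dendrogram type enforces this invariant.

Cuts take the k-1 highest merges; clusters are renumbered by first-leaf
index so labels are stable. Cluster-vs-annotation association uses the
Pearson chi-square test, replaced for 2x2 tables by the two-sided Fisher
exact test (minimum-likelihood convention: sum all tables with
probability <= observed) whenever any expected count is <= 5.

## Nearest-centroid subtype assignment

Probes are matched to centroid genes in the namespace the centroid file
itself declares (symbol / UniGene / Entrez; never guessed); multiple
probes per gene collapse by mean expression. By default each matched
gene is median-centered across the cohort before correlating — the
standard correction when single-channel cohort data are compared with
centroids derived from two-color ratios; `center="none"` exposes the
sensitivity. Every sample is assigned to the argmax-correlation subtype
(exact ties flagged and resolved alphabetically); no minimum-correlation
"unclassified" threshold is applied by default, matching the convention
of assigning every sample, with an optional `min_r`.

## Signature derivation

For a two-group contrast the pipeline computes per-probe Welch t
statistics (Welch–Satterthwaite df, two-sided p), screens at p < 0.01,
and reports the local false-discovery rate achieved at the screen
boundary. The local FDR uses the probit transform `z = Phi^{-1}(p)` so
the null component is exactly standard normal, and models the marginal
as `f(z) = pi0 * phi(z) + (1-pi0) * f1(z)` with `f1` a Gaussian-kernel
density (Silverman bandwidth, grid-binned for O(n) evaluation) whose
case weights `1 - tau_i` are re-estimated by EM together with `pi0`
(initialized by the Storey estimator at lambda = 0.5). On pure-null
input the estimator returns pi0 ~ 1 and lfdr ~ 1; on a pi0 = 0.8
mixture with alternative z ~ N(-2, 1) it recovers pi0 to within a few
hundredths (asserted at +-0.1 in the tests). Degenerate p-value vectors
(no spread) are flagged and given lfdr = 1.

The screened probes are then ranked by a random forest: a bagged
ensemble of decision trees with sqrt(p) candidate features per split,
scored by Breiman's out-of-bag permutation importance (per tree,
accuracy on its out-of-bag samples before vs after permuting one
feature; only features the tree splits on are perturbed). Defaults are
2,000 trees with each tree grown on a random 10% subset of the
candidate probes. The feature subsample is deliberate: with p >> n and
a handful of near-perfect separators, unrestricted trees stop after one
to three splits, most candidates are never used by any tree, and their
importances tie at exactly zero, leaving the tail of the top-200
ranking arbitrary. Growing each tree on a feature subset forces split
usage across the candidate set and stabilizes the ranking; with these
defaults 85–88% of planted differentially expressed probes are
recovered in the top 200 on the default synthetic cohort. An optional
label-permutation importance p-value filter exists (off by default);
the primary rule is top-`n_keep` by importance. All stochastic steps
require an explicit seed and are bit-reproducible given it.

Small-group caveat: for contrasts like 5-vs-69 the Welch reference
distribution is mildly anti-conservative (empirically ~1.5–2% of null
probes at nominal p < 0.01); at balanced moderate sizes the p-values
are uniform to Kolmogorov–Smirnov precision. Contrasts with a group
smaller than 4 emit a warning.

## Gene-set enrichment

One-sided hypergeometric over-representation only ("is the overlap
larger than chance"), computed via the log survival function so that
overlaps with p far below double-precision underflow remain finite and
rankable. Gene sets and the signature are intersected with the universe
first; the universe defaults to all annotated genes surviving the
intensity filter and is always overridable, since enrichment p-values
are only meaningful relative to an explicit universe. Raw p-values are
primary (matching how such tables are conventionally reported); a
Benjamini–Hochberg column is emitted alongside, clearly labeled.

## PCA and model-based clustering

PCA is covariance-mode on the log2 data (no per-gene standardization)
by default — the scale of log2 expression is already comparable across
genes and standardizing would up-weight flat genes; a correlation-mode
flag exists. Scores come from SVD of the column-centered matrix; each
component's sign is fixed by making its largest-magnitude loading
positive, so runs are deterministic. Group confirmation fits full-
covariance Gaussian mixtures by EM for k = 1..5 with ridge
regularization 1e-6, choosing k by BIC.

## aCGH calling and the perturbation rate

Replicate spots are dropped if flagged invalid, if either channel is
non-positive, or if signal-to-noise < 3; a clone-tumor measurement
becomes *missing* if no spot survives or if the surviving spots' log2
ratios spread with SD > 0.1; clones missing in strictly more than 50%
of tumors are excluded cohort-wide. Surviving clones get the median
Cy3/Cy5 ratio, and status by strict thresholds on the **linear** ratio:
amplicon > 2.0, gain > 1.2, loss < 0.8, else normal. The linear-scale
reading is deliberate: applied to log2 ratios those numbers would imply
a 2.3-fold gain bound and a logically impossible loss bound above zero;
they are the standard linear-ratio cut-offs. A `literal_log` flag
implements the verbatim log-scale reading for comparison.

Note that the two QC rules interact: a clone whose surviving replicates
are individually credible can still be discarded because their spread
exceeds the replicate-SD cap — the SD rule is applied after the
signal-to-noise rule, on whatever spots survive it.

The genomic perturbation rate of a tumor is the *unweighted* mean over
chromosome arms of (altered clones) / (informative clones) per arm,
where altered = {loss, gain, amplicon} and informative = non-missing;
arms with no informative clone are excluded from the mean. Clones map
to arms by their single position; a clone exactly at the centromere
belongs to q. Arm weighting means a fully altered small arm counts as
much as a fully altered large one — the statistic measures how *widely*
the genome is perturbed, not how many megabases.

## IHC scoring and contingency tests

Scores: 0 = no stained tumor cell; 1 = 1–10% stained; 2 = 11–100%,
independent of intensity. Positivity: ER/PR/AR at score 2 only (the
black-box convention for hormone receptors); GGT1, GCDFP15, EGFR and
PTEN at score >= 1 (for GGT1 this encodes the 1% stained-cell
threshold); ERBB2 at Herceptest +++ (configurable). Rows scored "nd"
are excluded from denominators. The shipped 17-tumor table (15 Cowden
plus the two non-Cowden apocrine carcinomas) reproduces the published
counts exactly: GGT1 12/15, GCDFP15 8/15, PTEN-negative 13/15, classic
apocrine histology 4/15, ER-negative 4/15 (26.7%). Cowden-vs-control
p-values computed on the reconstructed 84-tumor panel (control counts
as published inputs) are reported as computed — the original full-panel
denominators differ per marker, so printed p-values of that study are
matched in magnitude, not asserted digit-for-digit.

## Synthetic generators

The expression generator emulates a 74-sample familial cohort: samples
multinomial over the five intrinsic subtypes (luminal A .35, luminal B
.20, basal .20, HER2 .15, normal-like .10 — typical cohort proportions)
plus 5 molecular-apocrine samples (3 labeled Cowden) over-expressing an
84-probe block. Probe value = baseline + class offset + block offset +
N(0, sd) noise on the log2 scale. Defaults: effect 1.5 log2 units
(~2.8-fold, typical of intrinsic marker genes), noise SD 0.5 (typical
residual spread of RMA-processed arrays), 20,000 probes of which 100
controls and 60 markers per subtype; planted probes get baselines in
[10, 12] — high enough to survive the intensity filter but inside the
ordinary expressed range, since a top-band baseline would mechanically
depress rCV (= sd/mean) and bias the selection window against them. A matching centroid
table (UniGene namespace) is emitted. Deliberately **not** emulated:
probe-level (PM/MM) structure, batch effects, correlated co-expression
modules beyond the planted blocks, missing values. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated model, not robustness to real-array artifacts.

The aCGH generator distributes clones across 22 autosomes
(length-proportional, even spacing; approximate physical lengths and
centromere positions built in) in quadruplicate spots, with planted
whole-arm or focal segments at true ratios 0.5 / 1.0 / 1.5 / 3.0 and
log-normal spot noise (default 0.05 log2 units); 5% of spots get
sub-threshold signal-to-noise plus heavier noise so the QC filters have
work to do. The default planted scenario (gains of 1q and 8q, losses of
10q and 16p, amplicon on 17q) yields a planted perturbation rate of
~0.11. The IHC generator draws per-marker positivity by group from
stated probabilities (defaults estimated from the shipped table) and
fills percent values uniformly within the implied score band, so every
generated row is self-consistent under the scoring rules.

Identical seeds give byte-identical outputs; different seeds share the
truth structure with fresh noise.

## Pipeline and reproducibility

The end-to-end runner takes a single YAML config, validates every
threshold range up front, requires a seed whenever the stochastic
supervised stage will run, and writes a manifest with versions,
thresholds, per-stage counts and SHA-256 hashes of all tabular outputs;
re-running the same config reproduces the hashes exactly. Problem sizes
in the test suite and acceptance script (20,000-probe cohorts, 10–20
seeds for branch-recovery rates, 500-sample centroid cohorts, 500–5,878
clone genomes) were chosen to make each recovery statistically
unambiguous while keeping a full run in the tens of seconds.

## Known limitations

- RMA normalization, MANOR spatial correction and GLAD segmentation are
  upstream of this package: the expression matrix and clone ratios are
  taken as provided.
- The local-FDR estimator assumes a unimodal alternative on the probit
  scale; strongly bimodal alternatives may split weight with the null.
- Fisher/chi-square switching uses the expected-count rule for 2x2
  tables; r x c tables always use chi-square (with a sparsity warning).
- The perturbation rate ignores tumor-cell content; contamination by
  normal cells attenuates losses, which no QC rule here corrects.
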