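# Methods

## Data model

Expression values are log2-scale intensities in genes × samples matrices
with unique identifiers and no missing entries (the loader rejects missing
or non-numeric cells rather than imputing; post-normalization array data
are complete, and imputation is out of scope). A paired study holds one
matrix per tissue over an identical, identically ordered gene list plus a
design table giving, per subject, the tissue-A and tissue-B sample ids and
the covariates age (years), sex (0/1) and smoking status (0 = never,
1 = current). All tabular I/O is TSV (UTF-8, `.` decimal, no quoting) with
floats at six significant digits, so files round-trip byte-identically.

An expression filter keeps genes whose median log2 intensity is strictly
greater than 3 (strict, so a gene sitting exactly at the threshold is
dropped). Standardization is per gene to mean 0 and sample SD 1; the n − 1
denominator is used for every SD and correlation in the package.
Multiple-testing adjustment is Benjamini–Hochberg step-up throughout
(statsmodels' implementation behind the package's `bh_adjust` surface;
the test suite checks it against an independent brute-force step-up).

## Concordance

Per gene, Spearman ρ between the subject-ordered tissue values, computed
as Pearson correlation of average ranks (tie-corrected). P-values use the
t approximation `t = ρ√((n−2)/(1−ρ²))` with n − 2 df — standard and
adequate at n ≈ 77; the tests compare it with exact permutation
enumeration at n = 7. Genes constant in either tissue have undefined ρ and
are flagged and excluded from the FDR universe.

The pairing permutation test counts "positively correlated" genes under
the true pairing and under B uniform relabelings of the tissue-B samples
(identity permutation included; its probability is negligible). The
qualifier is configurable because "positively correlated" is ambiguous:
`p05` (ρ > 0 and unadjusted p < 0.05, the default), `positive` (ρ > 0
only) or `q05` (ρ > 0 and BH q < 0.05). The reported
`p = (1 + #{null ≥ observed})/(B + 1)` is never below 1/(B+1). With a
discrete count statistic the p-value is slightly conservative; the null
calibration test uses the `positive` qualifier on many genes, where the
statistic is fine-grained enough for a Kolmogorov–Smirnov uniformity
check.

Profile correlations are Spearman across genes for every
(tissue-A sample, tissue-B sample) pair; matched (diagonal) and
mismatched entries are compared with a two-sided Mann–Whitney rank-sum
test — distribution-free, since no parametric form is claimed for the
profile-correlation distributions. Group summaries report per-gene mean
and SD pooled over both tissues' samples and compare concordant with
non-concordant genes by the same rank-sum test; with a single group the
comparison is reported as NaN rather than guessed.

## Paired differential expression

The tissue contrast is fitted on within-subject differences, where subject
effects cancel exactly — a subject fixed-effect model would make
per-subject covariates collinear, while the difference model is equivalent
for the tissue contrast and unambiguous. Covariates are mean-centered by
default so the intercept is the average tissue effect (the reported
log2FC) regardless of covariate coding; `center_covariates=False` is
available when the covariate-zero baseline shift is wanted instead.
Inference is ordinary least squares with n − 4 residual df, vectorized
across genes; no empirical-Bayes variance moderation is applied (moderated
engines change per-gene p-values in ways that are hard to pin down; a
plain t keeps the model fully specified). Genes fitted perfectly get
t = 0 when the estimate is 0, p = 0 otherwise. A gene is a DEG when
q < α and |log2FC| strictly exceeds the fold-change threshold
(default 2, a flag, since published fold-change conventions vary).

## Shrinkage GGM and the edge test

The sample correlation matrix of standardized data is shrunk toward the
identity with the analytic optimal intensity

λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²,
Var̂(r_ij) = n/(n−1)³ Σ_k (w_kij − w̄_ij)², w_kij = x_ki x_kj,

clipped to [0, 1]. A zero denominator (all sample correlations exactly
zero) maps to λ = 1: with no signal to preserve, full regularization is
the continuous limit. `R(λ)` has smallest eigenvalue ≥ λ, so the inverse
exists for any λ > 0; the inversion uses a Cholesky factorization and a
failure at λ = 0 on rank-deficient data raises an error suggesting
shrinkage.

Shrinkage compresses the partial correlations onto ±(1 − λ). The edge
test uses the scaled-Beta null: under H₀, `u² = (r/(1−λ))²` follows
Beta(1/2, (κ−1)/2), equivalently a null density ∝ (1 − u²)^((κ−3)/2).
At λ = 0 and κ = n − 1 this is exactly the classical sample-correlation
null (t transform with κ − 1 df), which the tests verify; the general
case is validated against a 10⁶-draw Monte-Carlo simulation of scaled
null draws rather than trusted on its own.

κ is an *effective* degrees-of-freedom parameter: the nominal value
n − 1 − (p − 2) is negative whenever p ≫ n, so the default (`fit`)
maximizes the null log-likelihood of all observed partial correlations
over κ ∈ (3, 10n], assuming the edge population is predominantly null —
reasonable for sparse networks, and the choice that makes the null
p-values empirically uniform on edge-free data. A fixed numeric κ is
accepted for small or known-df problems (`estimate_kappa` needs at least
30 edges to fit; below that, pass a value). When every partial
correlation is ~0 the likelihood is maximized at the upper bound and a
warning is emitted. Networks keep edges with BH q ≤ threshold.

## Network comparison

Edges are unordered pairs with lexicographically sorted endpoints.
Overlapped edges are those significant in both tissues; gene-level classes
are connected-in-A/B, any-edge, common-edge (endpoint of an overlapped
edge) and isolated. Because published summaries divide by different
things, `summarize_counts` emits every count next to an explicit
denominator: connected and any-edge gene percentages over the universe,
common-edge genes over both the any-edge count and the larger tissue's
connected count. Percentages are rounded half-up to two decimals. The
edge scatter reports −log10 BH q per tissue for every pair significant in
at least one tissue, with q floored at 10⁻³⁰⁰ before the logarithm
(double-precision p-values underflow to zero for the strongest edges).

## Enrichment and sampling contrast

Overrepresentation is the one-sided hypergeometric upper tail per term
(terms intersected with the user-supplied universe first), BH-adjusted
across terms. External enrichment services with ontology-aware corrections
are deliberately not emulated: term databases drift, and the part worth
keeping is the *sampling contrast* — N same-size gene sets drawn uniformly
without replacement from the parent list and from the genome universe,
with the per-term mean, SD and standard error of −log10 p over draws
reported next to the observed value (both spread measures, since "±2
standard errors of the mean" and "±2 SD of the draw distribution" answer
different questions). When the query exceeds half its parent set, parent
sampling is skipped and flagged: the draws would largely reproduce the
query. The per-sample gene-set score is the mean of member-gene z-scores
(genes standardized jointly across all samples) — a transparent stand-in
for kernel-density gene-set variation scores that preserves
between-tissue contrasts at a fraction of the complexity, and is labelled
as such in the output.

## Synthetic data

The generator plants ground truth in disjoint gene blocks by default so
recovery is attributable: concordant genes share a latent subject effect
with loading `a = σ√(ρ/(1−ρ))`, giving cross-tissue correlation exactly
ρ_target; the remaining genes are drawn independently per tissue from a
zero-mean multivariate normal whose precision matrix has ±edge_strength
off-diagonals at edges sampled uniformly without replacement
(Erdős–Rényi G(n, m)) and diagonals set to row-absolute-sum + 1 (strict
diagonal dominance ⇒ positive definite). The two tissues' edge sets share
⌊s·m⌋ edges. DE genes get a mean shift in tissue A only; smoking genes a
covariate shift in both tissues. Covariates: age ~ U[20, 60], sex and
smoking balanced Bernoulli — a roughly balanced adult cohort. All
randomness flows from one seed through a single generator, so output is
byte-identical per seed.

Default edge_strength is 0.9, chosen so planted edges have partial
correlations near 0.3 — strong enough to be detectable at realistic
sample sizes without being trivial. The generator emulates the *design*
(matched pairs, sparse partial-correlation structure, covariates), not
microarray physics: no probe-level noise, batch effects, mean-variance
trends or heavy tails. Tests passing on this generator demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-array artifacts.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problems chosen to give the
checks adequate power: 1000 genes × 60 subjects × 500 permutations for the
pairing bound (10 replicates), 100 genes × 77 samples (4950 edges) for
null-edge calibration, 30 genes/20 edges at n = 77 for recovery, 10⁶
draws for the Monte-Carlo null oracle. Beta tails use scipy's regularized
incomplete beta; κ optimization is bounded Brent with xatol 10⁻⁶;
symmetry of partial-correlation matrices is enforced by averaging with
the transpose (numerical asymmetry ≤ 10⁻¹⁰).

## Known limitations

GGMs capture only linear conditional associations. The κ fit assumes a
predominantly null edge population; on densely connected gene sets it
will be biased toward heavier-tailed nulls and conservative edge calls.
The BH threshold controls FDR among edges, not the probability that the
network contains no false edge. The per-sample set score ignores
gene-gene correlation within sets. The generator's disjoint-block layout
means concordance and network recovery are tested separately; an
`allow_block_overlap` flag exists for mixed scenarios but ground-truth
attribution is then ambiguous.
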