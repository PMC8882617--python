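# Methods

This note documents the statistical models behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Inheritance-mode classification

For each gene the F1 replicate vector is tested against per-replicate
mid-parent values, MPV_r = (P1_r + P2_r)/2, with a two-tailed
pooled-variance (homoscedastic) t-test. p ≥ α (default 0.05) is called
*additive*; otherwise the F1 sample mean m decides the nonadditive mode:
m above the larger parental mean is *over-dominance*, below the smaller
is *under-dominance*, otherwise *dominance* ("between" is the closed
interval, so an exact tie with a parent mean counts as dominance — a
measure-zero case under continuous noise).

Pairing MPVs by replicate index preserves the replicate count and the
homoscedasticity assumption; the alternative of testing F1 replicates
against the pooled 2n parental replicates would mix two parental variance
components into one group. The pairing choice is recorded in the run
summary settings. Classification is intended for genes already flagged
as differentially expressed, but `classify_inheritance` accepts any trio
so it can be tested standalone.

Degenerate inputs: when both the F1 and MPV vectors have zero variance,
equal means give p = 1 (additive) and unequal means give p = 0 with a
warning, since the pooled-variance statistic is undefined there.

## Seven-way regulatory divergence

Cis-acting variants travel with their allele and survive as allelic
imbalance inside the hybrid; trans-acting variants act on both alleles
and appear only as divergence between the parents. Three decisions per
SNP capture this:

* **P set** — chi-square goodness-of-fit of the parental allele ratio
  against 1:1. Parents are homozygous, so the ratio crosses libraries:
  parent-1 allele counts from the P1 library over parent-2 allele counts
  from the P2 library, scaled to equal library sizes first. Replicate
  counts are pooled (summed) before the test.
* **H set** — the same chi-square on replicate-pooled hybrid allele
  counts.
* **T set** — two-tailed pooled-variance t-test between per-replicate
  hybrid log2 allelic ratios and per-replicate parental log2 ratios
  (ratios use a Haldane–Anscombe pseudocount of 0.5 so they remain
  finite at zero counts).

With significance at p < 0.05 per set, (P, H, T) = (+,+,−) is cis-only,
(+,−,+) trans-only, (+,+,+) cis+trans or cis×trans by agreeing/opposing
ratio signs (written `cisxtrans` in all outputs to keep files ASCII),
(−,+,+) compensatory, (−,−,−) conserved, and every other combination
ambiguous. A zero log2 ratio in the all-significant cell has no sign and
degrades to ambiguous with a warning.

SNPs enter the classifier only if they (a) are confirmed by an
independent genomic evidence set (VCF, 1-based positions preserved
end-to-end), (b) show divergent parental alleles in every parental
replicate (each parent's own allele is its strict majority), (c) are
heterozygous in every hybrid replicate (≥ 1 read of each allele;
configurable), and (d) carry total depth ≥ 20 in every hybrid and
parental replicate. Gene-level calls take the modal SNP pattern when its
proportion is ≥ 0.60, with deterministic name-order tie-breaking for the
reported modal pattern; otherwise the gene is *unassigned*.

Pooling replicate counts before the chi-squares treats replicates as
technical expansions of one sampling process; the T-set works on
per-replicate ratios and therefore carries the replicate-level
variability. Both conventions are emitted in the run summary settings.

## Differential expression and enrichment

The DE stage is deliberately count-free: a two-sample homoscedastic
t-test on log2(FPKM + 1) with Benjamini–Hochberg adjustment
(statsmodels), because the downstream contracts consume only
(log2FC, q, filter flags). Externally computed p-values (e.g. from a
count-based negative-binomial engine) can be passed through
`external_p`, keeping the filter semantics identical. A gene passes iff
max(group means) > 1 FPKM, q < 0.05, and |log2FC| > 1. The FPKM filter
uses the larger group mean — requiring expression in at least one
condition — and the choice is noted in the output settings. Fold changes
use a pseudocount ε = 0.01 FPKM, negligible for expressed genes but
keeping log2FC finite at zero means. PCA is a gene-centered SVD of the
log2(FPKM + 1) matrix with no unit-variance scaling. Term enrichment is
an upper-tail hypergeometric test with BH adjustment over terms; no
ontology database is shipped — any term → gene-set map works.

## Weighted co-expression networks

Genes with mean FPKM ≤ 1 across samples are removed; the unsigned
adjacency is a_ij = |cor(x_i, x_j)|^β with β a config input (9 by
default, 6 for the DAP8 stage, following the study design; no scale-free
fit is performed). The topological overlap is

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with k_i = Σ_{j≠i} a_ij, and 1 − TOM is the clustering dissimilarity.

**Tree cut.** Instead of the published dynamic tree-cut heuristics the
package uses a deterministic static cut: among the dendrogram's merge
heights, it picks the cut maximizing the number of clusters that are
both large enough (≥ min_size, default 50) and coherent, breaking ties
toward the cut that covers the most genes. Coherence means the cluster
eigengene explains ≥ 0.2 of the standardized variance: a pure-noise
cluster of n genes over s samples has leading-eigenvalue share near the
Marchenko–Pastur edge (1 + √(n/s))²/n ≈ 0.09–0.12 at n = 50–100, s = 24,
while a genuine module with loadings ≥ 0.6 sits well above 0.3. The
coherence gate is what prevents loose aggregates of background genes
from surfacing as modules at coarse cut heights.

**Merging and membership.** Module eigengenes (unit-norm first right
singular vector of the row-standardized module submatrix, sign aligned
with the module's mean profile) are compared pairwise; while any pair has
dissimilarity 1 − cor < merge_cut (default 0.15) the closest pair is
merged and eigengenes recomputed. Merging is idempotent. A final
membership pass returns genes with |cor(gene, eigengene)| < 0.3 to
*unassigned* — the counterpart of kME-based cleanup in standard
co-expression workflows.

**Traits and hubs.** Module-trait association is a Pearson correlation
of eigengene scores with each trait (pairwise-complete over missing
values, retained n reported), significant at p < 0.05. Hub ranking uses
intramodular connectivity k_i = Σ_{j ∈ module, j≠i} a_ij on the
soft-thresholded adjacency; `use_soft=False` switches to raw |cor| sums,
and the whole-network connectivity over all assigned genes is reported
alongside (`k_total`) since both scopes are defensible. Ties break on
gene id. Edges with TOM ≥ 0.20 are exported once per pair in matrix
order.

## Synthetic-data generator

The generator is the package's test instrument: it plants ground truth
under exactly the structure each stage assumes, so passing tests mean
"the implementation recovers what its model says it should," not that
real tissue data are this clean.

* **Allele counts.** One SNP per gene; per replicate the hybrid depth is
  drawn around `read_depth_per_snp` (200 by default) and the allele-1
  count is Binomial(depth, 2^c/(1 + 2^c)). Parents are two homozygous
  libraries whose mean depths differ by 2^(c+t), split symmetrically.
  Depth draws are Poisson by default (`nb_dispersion = 0`): the pooled
  parental chi-square tests two independent counting processes against
  1:1, and Poisson sampling is the null under which that test holds its
  nominal level. Positive `nb_dispersion` (variance = m + φm²,
  method-of-moments) adds biological overdispersion, under which the
  parental test is knowingly anticonservative — useful for robustness
  studies, not for calibration checks. Category effect map (c = cis,
  t = trans, defaults ±2 log2 units, signs alternating by gene):
  cis-only (c, 0); trans-only (0, t); cis+trans (c, t) same sign;
  compensatory (c, −c); conserved (0, 0); cis×trans uses t = −(c + |t|)
  so that the two *observable* axes — hybrid ratio c and parental ratio
  c + t — both have magnitude 2 with opposite signs. (A naive (2, −2)
  pair is exactly compensatory, which the category map excludes for
  cis×trans.)
* **Trio expression.** Parent means μ1 ~ U(2, 10), μ2 = 3μ1; F1 means
  are mid-parent (additive), μ1 + w(μ2 − μ1) with w = 0.75 (partial
  dominance), μ2·2^δ (over-dominance) and μ1·2^−δ (under-dominance),
  δ = 1 by default. Replicates multiply the mean by lognormal noise
  2^N(0, noise_sd), matching positive, right-skewed FPKM values;
  noise_sd defaults to 0.1 log2 units. Dominance is planted at w = 0.75
  rather than complete dominance (w = 1) because an F1 mean exactly at
  the high parent sits on the classifier's over/dominance decision
  boundary and is unrecoverable from finite replicates; w = 1 remains
  available for boundary studies.
* **Modules and traits.** One latent factor per module, i.i.d. N(0, 1)
  across 24 samples (8 genotypes × 3 replicates); a module gene is
  λ·factor + √(1 − λ²)·noise with λ = 0.9 (0.98 for the 10 planted hubs
  per module), background genes pure noise. The latent signal is mapped
  affinely (10 + 2z, floored at 0) onto an FPKM-like scale: the affine
  map preserves all pairwise correlations exactly, so expected
  within-module correlation is λ² = 0.81, and every gene clears the
  mean-FPKM filter, keeping the filter and the clustering concerns
  separate. Each of the four kernel traits equals one module factor plus
  N(0, 0.1) noise.

What the generator does **not** emulate: multiple SNPs per gene with
shared errors, mapping bias, library-size imbalance, correlated
replicate effects, mean-variance trends across the dynamic range,
overlapping or nested modules, and trait structure beyond one factor per
trait. Recovery rates on this generator are therefore upper bounds on
real-data performance.

## Problem sizes and reproducibility

The shipped validation runs use 100 genes per regulatory category at
200× depth, 2,000 additive plus 1,000 strong-effect trio genes, five
60-gene modules with 100 background genes over 24 samples, and 1,000
Monte-Carlo repetitions for null-trait calibration — sizes at which the
binomial/sampling envelopes around the expected rates are a few percent,
so recovery thresholds are meaningful but runs stay interactive. Every
source of randomness flows from a single integer seed through
`numpy.random.default_rng`; repeated runs at the same seed produce
byte-identical outputs, and each output file of the pipeline driver
records the seed and a hash of the resolved configuration.

## Known limitations

* The static tree cut is a deterministic stand-in for the published
  dynamic tree-cut algorithm; it recovers well-separated planted modules
  but does not reproduce that algorithm's behavior on nested or
  unbalanced dendrograms.
* Background genes whose chance correlation with a module factor exceeds
  the kME threshold can be absorbed into modules (module purity is not
  guaranteed, only recovery of planted memberships).
* The per-SNP tests assume independent sampling per library; PCR
  duplicates or shared lane effects would invalidate the chi-square
  calibration in real data.
* The count-free DE test is a pragmatic substitute for count-based
  engines; with few replicates it is less powerful than
  dispersion-shrinking methods, and users with count data should supply
  `external_p`.
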