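# Methods

## Study design and hardiness index

The default design has four genotypes — M, WM, SN, N, i.e. a spring wheat,
its winter near-isogenic line (NIL), the spring NIL of a winter wheat, and
that winter wheat — each under cold treatment and control with three
biological replicates (24 samples). Freezing tolerance per genotype is the
LT50 from an artificial freeze test (defaults −8.3, −13.2, −13.0, −21.7 °C).
The cold-hardiness index is

    H = LT50 / (−25)

with −25 °C taken as the temperature below which most wheat genotypes
perish, so H ∈ (0, 1) on the meaningful LT50 range and larger H means
hardier. LT50 ≥ 0 is a domain error; LT50 < −25 °C is allowed but flagged
(H > 1). The index is linear by construction; no rounding is applied
internally.

## DEG criterion

Status per gene per contrast: 1 if log2FC ≥ 2 ∧ padj ≤ 0.01 ∧
max(mean TPM of the two groups) ≥ 2; 2 symmetrically for log2FC ≤ −2;
else 0. All boundaries are inclusive. The abundance gate uses the two
*group means* (what a DE contrast actually compares); a per-replicate max is
available via `DegThresholds(tpm_mode="replicate")`. Genes present in the
expression matrix but absent from a contrast table get status 0 (logged);
a gene in a contrast but missing from the expression matrix is a hard
error, as is a non-finite log2FC at significant padj.

## DEFE series and named groups

Series P concatenates the four cold/control statuses in genotype order
M, WM, SN, N; series C and K concatenate the two winter-vs-spring NIL
contrasts (WM/M then N/SN) under cold and control respectively. The digit
alphabet is fixed at {0, 1, 2}. Queries use single-digit `*` wildcards.
Named groups are cross-series intersections:

- WHG = P0101 ∩ C11 ∩ K00, WHG_down = P0202 ∩ C22 ∩ K00
- SHG = P1010 ∩ C22 ∩ K00, SHG_down = P2020 ∩ C11 ∩ K00

SHG deliberately pairs P1010 with C22: genes induced by cold only in the
spring-habit genotypes sit *below* their winter-habit NILs in the
winter-vs-spring cold contrasts.

## Hardy / anti-hardy classification

Correlations are Pearson with a two-sided t p-value on n − 2 df (n = 4
genotypes), the default of the R ecosystem such analyses are usually run
in. Two vectors are correlated against H: the four cold/control log2FCs,
and the four replicate-averaged cold-treatment log2(TPM+1) means. Hardy
requires both correlations positive with p ≤ α (default 0.05) plus cold
mean > control mean in all four genotypes; anti-hardy requires a DEG *down*
call (status 2) in the hardiest genotype's cold/control contrast plus both
correlations negative — significance of the negative correlations is not
demanded by default (`require_anti_significance` turns it on). The two
labels are mutually exclusive by sign. With n = 4, p ≤ 0.05 implies
|r| ≥ 0.950 (`critical_r` computes the exact value); this makes the hardy
call deliberately stringent. A zero-variance (flat) profile makes the
correlation undefined; such genes are logged and labelled `none` rather
than crashing the run. Scale invariance of the labels holds exactly for
the fold-change vector and for the TPM means up to the +1 pseudocount in
the log transform — negligible at the abundances the generator produces,
but worth remembering for data near zero TPM.

## Association network

Nodes are the DEG-filtered genes plus (by default) the lipid traits.
Pearson correlation across the 24 samples is soft-thresholded,
a_ij = |r_ij|^β with β = 6 unsigned (the signed variant ((1+r)/2)^β is
available); β and signedness are recorded in output metadata. The
topological overlap matrix uses the unsigned variant with +1 in the
denominator (TOM_ii := 1). Edges are the top 1 % of upper-triangle TOM
weights: the cutoff is the m-th largest weight with m = ceil((1 − q)·pairs)
and all ties at the cutoff are kept, making the selection
order-independent. Hierarchical clustering is average linkage on 1 − TOM,
cut to 50 clusters by default (height cutting available). Cluster–trait
correlation summarizes each cluster by its eigengene — the first principal
component of the member rows after per-gene standardization, oriented to
correlate non-negatively with the cluster mean profile (cluster-mean
summaries available via `eigengene`-free correlation if preferred); traits
include the lipid species and five binary condition indicators
(cold treatment, winter habit, spring habit, and their cold-restricted
versions).

Subnetwork association strength is AS = (mean within-group degree over
nodes with ≥ 1 within-group edge) / n. The denominator population defaults
to the connected members, so AS measures cohesion among the nodes that
actually participate in the subnetwork; `all_members` additionally
penalizes isolated members and is available as an option.
AS ∈ [0, (n−1)/n], attaining the maximum on a
complete subgraph. Neighborhoods: immediate = neighbors of the seed set
minus seeds; secondary = neighbors of the immediate set minus both.

## Synthetic-study generator

Expression is log-normal: log2(TPM+1) = cell mean + N(0, σ), σ = 0.3 by
default, with per-gene baselines drawn from U(3, 8) (≈ 7–255 TPM, so the
abundance gate is comfortably met and the +1 pseudocount is negligible).
Planted signals on the cold cells, with effect e = 4.0 log2 units:

- WHG: +e in WM and N only; SHG: +e in M and SN only — exactly the P0101 /
  P1010, C11 / C22, K00 patterns at zero noise.
- hardy: +e·H_g/H_max per genotype g, so the planted log2FC and cold means
  are exactly linear in H and reach magnitude e in the hardiest genotype;
  anti-hardy is the negated version, giving a strong down call in N.

Defaults: 3000 genes with 60/60/60/40 planted WHG/SHG/hardy/anti-hardy,
224 lipid traits of which 10 per sign are tied positively/negatively to the
hardy and WHG mean profiles (the rest are N(0, 1) noise; trait units are
arbitrary, as lipidomics normalization is out of scope). TPM values are
2^x − 1 clipped at 0. Identical seeds give bit-identical bundles.

Contrast tables are fabricated by a **moderated two-sample t-test** on
log2(TPM+1): per-gene pooled variances are shrunk toward their across-gene
mean with 20 prior degrees of freedom, the statistic is referenced to a t
distribution with residual + prior df, and BH adjustment is applied across
genes per contrast. A plain Welch test at n = 3 per group was evaluated
first and rejected: its variance estimate is so unstable that genes with a
planted 4-log2 effect routinely land at padj ≈ 0.01–0.05 and drop digits
from their DEFE patterns. Variance moderation is exactly the dispersion
sharing that count-based DE tools rely on at such sample sizes, so the
moderated test is the more faithful stand-in for the DE tables the
pipeline is meant to consume.

What the generator does **not** emulate: count overdispersion and
library-size effects, correlated noise between replicates, realistic lipid
chemistry, or any background co-expression structure. Passing recovery
tests therefore demonstrates the pipeline's correctness under its stated
model, not performance on real RNA-seq data.

## PCA

One SVD of the row-centered (and, by default, row-standardized)
gene × sample matrix of log2(TPM+1) values serves both views: gene scores
(U·S) and sample loadings (V), with variance fractions σ_k²/Σσ².
Components are sign-canonicalized (largest-magnitude sample loading
positive), making scores reproducible across gene orderings. Constant
rows are an error under standardization and are reported by name.
Group separation is the silhouette score on the selected components plus
the centroid distance.

## Problem sizes and numerical choices

The shipped tests run the generator at 800 genes × 60 lipids for
parameter-recovery sweeps (seeds 1–10) and at the full 3000 × 224 scale for
one end-to-end run; these sizes give stable recovery statistics while
keeping the whole suite around ten seconds. At the default scale the
DEG set is ≈ 220 genes, so the thresholded network holds the top 1 % of
≈ 98 k node pairs; because TOM divides by each node's total connectivity,
the planted block with the fewest outside correlations monopolizes the
retained edges, and other planted groups can legitimately show AS = 0 at
this scale — at two orders of magnitude more nodes the same threshold
retains hundreds of thousands of edges and spreads across groups.
Ties in frequency tables break lexicographically; the top-1 % cutoff keeps
ties; TOM is clipped to [0, 1] against floating-point drift; correlation
p-values for |r| = 1 are set to 0 exactly.

## Known limitations

- The hardy classifier correlates 4 points; it is a screening rule, not an
  inference procedure, and no multiple-testing correction is applied across
  genes (matching standard practice for this screen).
- Lipid traits enter the network as plain rows; no lipid-specific
  normalization is attempted.
- β is fixed at 6 by convention; scale-free-fit-based selection is not
  implemented.
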