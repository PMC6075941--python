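# Methods

## Scope and shape

The package implements a two-condition (WT vs KO) signed weighted gene
coexpression comparison as a library (`src/conet/`) with thin narrative
drivers (`analysis/01..05`). Differential expression itself is *not*
computed here: DE results enter as a table of (gene, q-value, tissue, age)
rows produced upstream, and the package consumes them at the inclusive
threshold q ≤ 0.01. Interactive network visualization is out of scope; the
package exports plain TSV/SIF edge lists instead.

## Network model

Per condition, expression is a genes × samples matrix spanning all
(tissue, age) strata of that genotype. Correlation is the biweight
midcorrelation; it tolerates single-sample outliers that would dominate
Pearson correlation at n ≈ 60. When a gene's MAD is zero the biweight
transform is undefined and that gene falls back to mean-centered
(Pearson-style) deviations; constant genes get correlation 0 with a
warning. These choices keep the matrix defined on degenerate input without
silently changing well-behaved entries.

Adjacency is signed, `a = ((1+r)/2)^β`, so r = −1 maps to 0 and the sign
of the correlation is preserved — anti-correlated genes are *not*
neighbors. β is chosen as the smallest candidate (1..20) whose
connectivity distribution fits scale-free topology with R² ≥ 0.8 and
negative slope (10 log-spaced bins of k, regression of log10 p(k) on
log10 k̄).

Two failure modes of that criterion required a policy:

1. Data dominated by a few similar-size modules is not scale-free; the
   index then climbs slowly and monotonically with β, so "argmax over the
   grid" lands at β = 20 where the network is so sparse that noise
   correlations raised to the 20th power rival true module signal.
2. The index can first cross 0.8 at a similarly extreme β.

Both are handled by the conventional sample-size rule for signed networks
(β = 12 for n > 40, 14 for 31–40, 16 for 21–30, 18 otherwise): it serves
as the fallback when the target is never reached and as a cap when the
target is first reached above it. When the sample count is not supplied
the fallback is the best-fitting candidate, with a warning either way.

Topological overlap (TOM) is applied by default before clustering
(`tom: false` disables it); dissimilarity is 1 − TOM.

## Module detection

Average-linkage hierarchical clustering (scipy) followed by a
dynamic-hybrid branch cut authored in `conet.treecut` (no established
implementation of the dynamic tree cut is available in this environment,
and the cut is central enough to the artifact to be first-class, tested
code):

- Every non-root branch with ≥ `min_module_size` leaves is scored by its
  **relative gap** `(attach − top) / (attach − median internal height)`,
  where *attach* is the height at which the branch joins the rest of the
  tree and *top*/*median* summarize the heights at which its own members
  merged. The statistic is scale-invariant — it behaves identically
  whether dissimilarities span (0, 1) or are compressed near 1 by a large
  soft-threshold power — and a featureless (noise) dendrogram, which
  merges continuously, has no branch with a large relative gap anywhere.
- `deep_split` 0..4 maps to the minimum relative gap
  (0.30, 0.22, 0.15, 0.08, 0.03): conservative settings accept only
  strongly separated branches (pure-noise input stays ≥ 80–100%
  unassigned), aggressive settings split finer.
- Qualifying branches are selected greedily, largest first, skipping
  overlaps: among nested candidates (a module and a tight core inside it)
  the whole module wins, while a branch spanning two modules almost never
  qualifies because its internal top merge sits at its attach height.
- A PAM-like pass then assigns each unlabeled gene to its nearest module
  (lowest mean dissimilarity) if it falls inside that module's height
  envelope *and* is closer to the module than to the rest of the network.
- Optional merge step: modules whose eigengenes have correlation
  dissimilarity below `merge_height` (default 0.25) are merged
  iteratively, closest pair first.

Module labels are the conventional color palette in decreasing size order
(turquoise, blue, brown, …), grey reserved for unassigned genes. Known
limitation: a dataset that is one single module (or none) yields all-grey,
since a lone branch has no surroundings against which a gap can be
measured.

## Eigengenes, membership, hubs

Eigengenes are the first right-singular vector of the row-standardized
module submatrix (unit Euclidean norm over samples; sign aligned to the
module's mean standardized profile; zero-variance genes dropped with a
warning), with `propVarExplained = σ₁²/Σσ²`. kME uses the same correlation
estimator as the network (bicor by default, Pearson switchable). Hubs are
module members ranked by own-module kME, ties broken lexicographically.

## Module matching and emergent/lost calls

All pairwise WT × KO module overlaps are tested with the upper-tail
hypergeometric probability over the shared analysis universe (grey
excluded). Each KO module's best match is the smallest-p WT module (ties:
larger overlap, then smaller WT module). Colors are claimed greedily in
ascending best-p so each WT color is assigned at most once; a KO module
whose best p exceeds the Bonferroni-adjusted 0.05 threshold *or* whose
best color was already claimed by a stronger match keeps a fresh color and
is flagged emergent — the latter clause is what makes a module split
visible as "one half inherits the parent color, the other emerges". WT
modules never claimed are lost. The threshold is configurable; Bonferroni
was chosen as the default because the matching table is small and the
cost of a false "counterpart" call is high.

Overlap percentages are reported with both display conventions that
appear in practice: floor for lower-bound phrasing ("over 72%" for
148/204) and round-half-even for plain reporting ("5%" for 26/529).

## Preservation statistics

For each reference (WT) module of size q, seven statistics are computed
in the test (KO) data: density family — mean within-module signed
adjacency, eigengene variance explained, mean sign-aware kME, mean
sign-aware correlation; connectivity family — correlation of intramodular
connectivity vectors, of kME vectors, and of the vectorized within-module
correlation matrices (all restricted to the module's genes; `cor_kME` is
kept in the connectivity family with the same gene restriction for
consistency). The null re-computes all seven on `n_perm` uniform random
gene sets of size q from the filtered universe (no expression matching —
the generator's background genes have the same marginal scale as module
genes, so matching would be a no-op on synthetic data and is not claimed
for real data). Z = (obs − null mean)/null sd; Zdensity/Zconnectivity are
family medians, Zsummary their mean; medianRank ranks the *observed*
statistics across modules (rank 1 = most preserved), takes family medians
and averages the two. Equal-size gene sets share one null sample for
speed. Modules below 4 genes are skipped; n_perm < 20 warns.

Behavioral calibration (not bit-equivalence to any external tool) is the
validation target: planted intact modules score Zsummary > 10, random
gene sets |Zsummary| < 2 and ≈ N(0,1) Z, and the planted split module
ranks worst by medianRank. On homogeneous synthetic modules the
connectivity Z's are intrinsically weaker than density Z's — without a
spread of loadings a module has no within-module connectivity *variation*
to reproduce — which is why the generator draws loadings from a range
rather than a constant.

## Synthetic data generator

Gaussian latent-factor signal on the log scale: per condition, stratum
and module, a factor vector ~ N(0,1) across samples (factors are redrawn
independently per stratum while loadings are shared, so strata can be
concatenated into one multi-tissue multi-age network per genotype — the
same pooling the analysis applies to real data). Gene g in module m
observes `λ_g F_m + ε`, ε ~ N(0, σ²); background genes are pure noise.

Defaults (the study conditions of the validation suite; chosen once, a
priori, from a power analysis of the hub-shift margin):

- 500 genes in five modules of 100; 8 samples per (genotype, tissue, age)
  cell by default (the emulated 64-sample design); the recovery scenario
  (`recovery_spec`) uses 15 per cell = 60 per condition.
- loadings λ ~ U(0.3, 0.5), noise σ = 0.3: mean within-module pairwise
  r ≈ 0.6. Designated hub genes carry λ = 0.95, far enough above the bulk
  (max kME gap ≈ 0.6 Fisher-z units, ≈ 3 s.e. at n = 60) that the top-kME
  gene is the planted hub with high probability at any seed.
- split: module index 1, fraction 0.7 — in KO its genes are driven by two
  independent sub-factors (70/30 genes), the canonical "module
  disruption".
- hub shift: module index 2 swaps the loadings of its first two genes
  between conditions.
- DE: an additive shift of 1.0 on 40 genes of the split module in KO
  cortex at 4 months; truth DE tables give planted genes q = 1e-6, all
  others q = 1.0.
- markers: four cell types seeded at 50 markers each, purity 0.8, into
  modules 0 (neurons), 1 (endothelial), 3 (microglia), 4 (astrocytes).
- optional negative-binomial count layer, mean = 2^(baseline + signal)
  with baseline ~ U(4, 9) log2 units and dispersion 0.1 — present only to
  exercise the read-count filter; all network math runs on the continuous
  layer.

What the generator does *not* emulate: mean–variance coupling of real
RNA-seq, batch effects, correlated noise between strata, overlapping
module membership, and library-size variation. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure the
method assumes, not that real brain data satisfies those assumptions.

All draws come from one `numpy` Generator seeded by the spec; identical
seeds give byte-identical TSV/GMT outputs (all floats written as %.6g).

## Expression input handling

Transcript-level tables are collapsed to genes by keeping the transcript
with the highest mean expression across all samples (ties: lexicographic
transcript id, for determinism; the chosen transcript is recorded).
The expression filter keeps a gene when it has ≥ 10 reads in strictly
more than 90% of samples — "more than" read literally — either globally
or within at least one (genotype, tissue, age) stratum; the stratum
escape is what retains a gene completely silenced in one genotype.
Technical replicates stay as separate columns (averaging is available but
off by default, since the downstream correlation treats columns
exchangeably). The default network-input transform for count-scale data is
log2(x+1), configurable to none (the synthetic continuous layer is used
as-is).

## Problem sizes and numerical choices

The validation suite runs at 500 genes × 60 samples per condition with
n_perm = 200, sizes at which every planted feature is recovered with wide
margins while the full suite stays fast; the pipeline itself is O(p²)
memory in the gene count and is comfortable to ~15k genes on one machine.
Other conventions: hypergeometric/Fisher p-values clipped to (0, 1];
correlations clipped to [−1, 1]; kME of < 3 genes reported NA; Welch df by
Satterthwaite; BH adjustment step-up with clipping at 1; all
tie-breaks lexicographic.
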