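# Methods

`emts2pca` implements a two-stage strategy for finding and validating a
discriminating gene-expression signature in a *small* two-group tumor
series (typically 10–15 samples per subgroup in the learning set), followed
by blind, case-by-case classification of independent samples.  This note
describes the model, the decision rules, the numerical conventions, and the
choices made where the procedure was genuinely open.

## Stage one: signature search with internal cross-validation

### Combinatorial designs

The learning set (two subgroups, e.g. benign vs malignant histology) is
resampled into 10-sample designs: all half-matrices of `k = 5` samples per
subgroup are enumerated in lexicographic order of sorted sample ids, then

1. half-matrices whose samples all share one level of a binary confounder
   (e.g. etiology: sporadic vs radiation-induced) are removed, so no design
   can ascribe a confounder contrast to the subgroup contrast; and
2. a greedy scan of the enumeration order retains a set of half-matrices
   any two of which share at most `max_shared = floor(k/2) = 2` samples
   (a "more than 50% different" composition rule).  Greedy retention in a
   deterministic order makes the design list reproducible; the retained
   set is maximal but not optimized, and its per-sample coverage can be
   uneven — see "Known limitations".

Every retained half-matrix of one subgroup is paired with every retained
half-matrix of the other (Cartesian product).  A warning is emitted if some
learning sample appears in no design.  `k` and `max_shared` are
configurable for series of other sizes; with 5-sample halves every learning
sample of a 13+13 series appears in at least one design.

### Gene screening per design

**Permutation t filter.**  For each design, a two-sample pooled-variance t
statistic is computed per gene and referred to its exact permutation null:
all C(10,5) = 252 assignments of five samples to the first group are
enumerated, and `p = #{|t_perm| >= |t_obs|}/252`.  Genes with `p < 0.05`
survive.  This filter is deliberately weak — its job is to remove genes
that are plainly noise, not to pick the signature.  Genes with undefined t
(zero pooled variance) get `p = 1`.  A tiny relative margin (1e-9) in the
tie comparison makes the p-value exactly invariant to which subgroup is
labelled first.

**Three-state expression mixture.**  The surviving rows are centered to
mean 0 and scaled to unit Euclidean norm ("module"), pooled into a single
one-dimensional sample, and fitted by EM with a three-component Gaussian
mixture: an *under-expressed* and an *over-expressed* component sharing one
variance, flanking a *baseline* component with its own mean and variance.
The baseline component exists because the weak filter always lets through
genes carrying no subgroup signal, whose normalized entries concentrate
around zero; without it, a two-component fit inflates its variance to cover
that central mass and no entry is ever assigned confidently.  Each entry's
posterior probabilities of over- and under-expression, `P_over` and
`P_under`, are the responsibilities of the two deregulated states
*conditional on deregulation*, so `P_over + P_under = 1` holds exactly for
every entry, and an entry equidistant between two equal components scores
0.5/0.5.  This is the package's documented reading of a per-entry
over/under posterior; the mixture-of-three construction follows the
"probability of expression" tradition for microarray data.

The fit is deterministic: outer means start at ± the 75th percentile of the
absolute pooled entries, baseline mean at 0, weights (¼, ½, ¼), and all
variances at the pooled sample variance; convergence at relative
log-likelihood change < 1e-8, iteration cap 20 000 (the shared-variance
ridge can make the final approach slow; iterations are cheap — the E/M
steps are compiled with numba).  Non-convergence raises an error carrying
the log-likelihood trace.

**Candidate rules.**  A gene is a candidate of its design iff

1. every one of its 10 entries is confidently assigned:
   `1 − |P_under − P_over| < 0.05`; and
2. the majority component is "over" in all samples of one subgroup and
   "under" in all samples of the other (the direction is recorded).

Exact ties (`P = 0.5`) fail rule 1 by construction.  Empty candidate sets
are allowed and simply discard the design.

### Internal cross-validation ("training")

Each design, restricted to its candidate genes (rows centered/normalized
over the 10 design columns), defines a **training space**: the Cartesian
system of the three leading eigenvectors of its sample covariance.  The
eigendecomposition is computed through the SVD of the genes × samples
matrix; eigenvector signs are fixed (largest-magnitude component positive)
so projections are bit-reproducible, eigenvalue ties are broken by input
order, and the population convention (divisor = number of samples) is used
throughout.

The 16 held-out learning samples are projected into that space using the
design's own per-row means and modules — never refit — so their placement
cannot leak into the geometry.  Each is classified by the RMS rules below.
A design's **training matrix is validated** iff at least one held-out
sample is classified correctly and none incorrectly (unattributed and
rejected outcomes are neutral); `c(h)` counts its correct classifications.

A **continuation check** aborts the pipeline unless at least 90% of the
learning samples are correctly classified by at least one validated matrix
(boundary inclusive).  With no subgroup signal this check fails in the vast
majority of random series, which is the intended behaviour: the method
refuses to emit a signature from noise.

### Relevance compilation and the final signature

The **frequency of relevance** of gene *i* for learning sample *j* is

    F(i,j) = Σ_h g(i_h, j_h) · c(h) / Σ_h c(h)

over validated matrices *h*, where `g(i_h,j_h) = 1` iff matrix *h* contains
both gene *i* and sample *j*.  The denominator Σc (total weight) bounds F
in [0,1]; a per-sample alternative denominator Σ_h g(j_h)c(h) is
config-selectable (`relevance_normalization: tumor_weight`) for sensitivity
analysis.  `F(i)` and `F(j)` are the row and column means of F (over the P
learning samples and the N distinct candidate genes respectively), and the
signature keeps exactly the genes with

    F(i) >= mF + 2·vF

where `mF` and `vF` are the mean and population standard deviation of the
*per-sample* marginals `F(j)`.  Thresholding a gene statistic with
sample-marginal statistics is deliberate — it is the rule as published;
computing `mF`/`vF` from `F(i)` instead is available via
`relevance_marginal: f_i`.  An empty selection raises an error carrying the
F(i) distribution.

### Standardization (ξ)

For each validated matrix: per-row means and modules are computed **on the
design columns only**, each candidate-gene row is extended to all L =
learning + testing samples, and transformed with those design statistics.
ξ(i,j) is the mean of these standardized values over all validated matrices
containing gene *i*, restricted to the signature genes.  Because the row
statistics come from the design columns alone, the learning-sample geometry
is unchanged by the arrival of testing samples — the prerequisite for
honest case-by-case prediction.  (L is taken as the actual learning +
testing sample count of the series at hand.)

## Stage two: blind classification in the validation space

The eigendecomposition of ξ′ (ξ restricted to the learning columns) defines
the **validation space**; every column of ξ — learning and testing — is
projected onto its eigenvectors (coordinates Ψ).  Learning coordinates are
therefore independent of which testing samples are projected, and
classifying testing samples one at a time or all at once gives identical
decisions.

**RMS decision rules.**  For a subgroup g, `RMS_g(j)` is the root mean
square of the per-axis differences between sample *j*'s coordinates and the
subgroup-g barycenter of the learning samples, over the active axis set.
Given a query *k*:

- *Rejected* (space unusable): some learning sample lies farther from its
  own subgroup's barycenter than a learning sample of the other subgroup
  lies from that same barycenter — the reference RMS ranges interleave.
- Otherwise *k* fits subgroup g when
  `RMS_g(k) < max_j∈g RMS_g(j) + s·sd_j∈g(RMS_g(j))`, with multiplier
  `s = 1` by default ("taking the variance into account"; the multiplier is
  config-exposed because only the principle, not the formula, is fixed).
- Exactly one subgroup fits → *attributed*; both or neither → *unattributed*.

**Axis escalation.**  Samples are first classified on the three leading
eigenvectors; any left unattributed are retried with *all* axes; any still
unattributed are retried on the eigenvector subset (within the top 10, an
exhaustive 1023-subset search) that maximizes the ratio of between-centroid
to summed within-group variance of the learning coordinates.  Variances use
the population convention with group terms weighted by group size, so
`V_inter + Σ V_within = V_total` holds exactly on every axis set; ties in
the search favour fewer axes, then lexicographic order.  A previously
attributed sample whose decision would change under the selected subset is
logged as a warning and kept at its original decision.

## Evaluation

Predictions are three-category (correct / misclassified / unclassified), so
reports are scored with the relative predictive efficiency
`RPE = correct / predicted` and the general predictive efficiency
`GPE = correct / all samples`, pooled over subgroups; `0 ≤ GPE ≤ RPE ≤ 1`
whenever defined, and both are invariant to swapping subgroup labels.
Sensitivity/specificity are available after explicitly naming the positive
subgroup and collapsing misclassified + unclassified into the negative
call.  Evaluators take count objects, so published count tables can be
scored directly.  Note on the worked examples: the published count row for
the post-Chernobyl series (5 + 6 correct) is inconsistent with the
accompanying text (12 of 13 correct) and with the printed score 0.92; the
text's counts are used, and 12/13 = 0.92 confirms them.

## Synthetic data

The generator emulates the data structure the method assumes: two subgroups
sharing `n_signature` oppositely regulated genes (per-gene orientation
fixed, mean ±`effect`), a binary etiology label driving `n_confounder_genes`
genes of its own, and a Gaussian background (`noise_sd`, a Student-t option
behind `heavy_tailed`).  Per-sample heterogeneity is modelled as *per-entry
replacement*: each signature entry is independently replaced by pure
background noise with probability `heterogeneity`, mimicking genes whose
expression varies within a subgroup.  Defaults are the reference study
conditions used by the test suite: 2000 genes, 50 signature genes, 30
confounder genes, 13+13 learning and 14+14 testing samples, `noise_sd 0.3`,
`effect 0.9` (= 3 × noise sd; after per-row normalization only this ratio
matters), `heterogeneity 0.2`, etiology fraction 0.5.  The generator does
not model probe-level dye effects, array batches, or intensity-dependent
variance; tests passing on it show that the machinery behaves as specified
under its assumptions, not that real tumor series satisfy them.

## Reference behaviour at the default study conditions

Across seeds at the defaults, roughly 110–160 designs survive the filters,
of which typically 65–90% validate; blind testing classification is
essentially perfect (no misclassifications among attributed samples in any
observed seed) and the selected signature is almost pure (precision ≈ 1).
Signature *recall*, however, sits near 0.4–0.55, not near 1: with 20%
per-entry heterogeneity a planted gene has on average ~5 of its 26 learning
entries replaced by noise, the candidate rules demand a unanimous confident
split across all 10 entries of a design, and the selection threshold
`mF + 2vF` is by construction at or above the grand mean of F — so planted
genes corrupted in many samples are systematically missed.  This is a
property of the selection rules under heterogeneity, not a numerical
defect: the same runs classify every blind sample correctly with the
partial signature they do recover.

## Known limitations

- The original patented "melting model" EM is not described publicly; the
  three-state mixture above is this package's documented substitute and
  makes no claim of equivalence.
- Greedy half-matrix retention is deterministic but can cover learning
  samples unevenly, which inflates the spread of the F(j) marginals and
  hence the selection threshold.
- Series whose subgroups are too small for disjoint-enough half-matrices
  (fewer than ~10 samples per subgroup at k = 5) yield too few designs for
  the continuation check; reduce `half_size` for such series.
- The eigenvector-subset search is exhaustive over the top `max_axes = 10`
  axes (1023 subsets); the exponent makes larger values impractical.
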