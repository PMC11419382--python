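# Methods

## Relative evolutionary rates

A gene's branch length on a given branch confounds (i) the branch's
genome-wide time/rate profile, (ii) the gene's overall evolutionary rate,
and (iii) the branch-specific deviation that carries covariation signal.
`ratecov` isolates (iii) with a centered log-ratio: per clade, the master
profile A_b is the arithmetic mean branch length over the genes present on
branch b (mean rather than median, matching the "genome-wide average"
convention; a branch supported by fewer than `min_genes_per_branch = 10`
genes is flagged unusable). Then

    raw[g,b] = ln((L[g,b] + ε) / (A_b + ε)),   R[g,b] = raw[g,b] − mean_b raw[g,·]

with ε = 1e-6 substitutions/site added to numerator and denominator so
zero-length branches (common on short branches) remain usable rather than
being discarded. Genes with fewer than 4 usable branches are dropped (the
downstream Fisher weight √(n−3) needs n ≥ 4). Properties: each retained
row means to zero within 1e-10, and R is invariant to scaling a gene's
whole row by any c > 0 (exactly when ε = 0 and lengths are positive).

The centered log-ratio was chosen over a regression-residual RER (the
RERconverge style) because it is the minimal transform that removes both
the branch profile and the gene's overall rate in one step and makes the
downstream Pearson correlation location/scale clean; the residual approach
is a known alternative that additionally absorbs heteroskedasticity in
branch-length variance, which the log scale already largely stabilizes.
Note one consequence of estimating A_b from the data: a module that
accounts for a large fraction of all genes leaks its shared factor into
the master profile and attenuates its own recovered correlation, so
analyses (and the test suite) keep focal modules small relative to the
gene universe, as they are in real genomes.

## Integrated ERC

Per clade, a gene pair's ERC is the Pearson r of their RER vectors over
the branches where both are present (requiring at least `n_min = 5` shared
branches — the clade datasets here have tens to hundreds of branches, so
5 is a permissive floor that still excludes meaningless 2–4-point
correlations; pairs with a zero-variance vector are treated as absent for
that clade). Each clade's r is mapped to

    z = atanh(clamp(r, ±(1−1e-6))) · √(n − 3)

— the variance-stabilized Fisher transform, which is approximately
standard normal under independent evolution regardless of n, so clades
with different branch counts contribute on a common scale. The integrated
FtERC of a pair is the plain (unnormalized) sum of z over its qualifying
clades. Two consequences are intentional and documented rather than
corrected: pairs observed in more clades can reach larger |FtERC|, and the
null SD of a k-clade pair is ≈ √k (≈ 2.24 at five clades), which is what
makes the conventional "mean + 2 SD ≈ 3" elevation threshold meaningful on
a five-clade genome-wide score distribution. Plain atanh(r) summation is
available via `build_erc_matrix(branch_weight=False)` for sensitivity
analysis. An absent pair (no qualifying clade) is distinct from a pair
with score 0.

The genome-scale pair loop is implemented with indicator-matrix products
(pairwise-complete sums via matmuls), so a 500-gene × 5-clade matrix
builds in well under a second.

## Permutation tests

One-group test: the observed mean over the set's scored pairs is compared
with `n_perm` random same-size draws from the universe of genes having at
least one scored pair. p is the plain proportion of null means ≥ observed
— not (k+1)/(N+1) — and a zero count is reported as the floor
"<1/n_perm" (1×10⁻⁵ at the conventional 100,000 permutations) with a
`p_is_floor` flag rather than a literal 0. Replacement draws include the
tested genes themselves (the universe is the whole scored proteome);
`exclude_group=True` is available. Draws are distinct within a draw and
independent across draws.

Two-group test: observed mean over cross-set pairs (self-pairs excluded);
both replacement schemes are run (hold A randomize B, and the reverse) and
the larger p is reported, with both one-sided sub-results retained.

Reported alongside p: the distance of the observed mean from the null mean
in null-SD units (`sd_distance`), the natural effect size for these tests.

## Top-quantile enrichment

From the list of a focal set's scores against the genome, the top
⌈q·N⌉ pairs are taken (q = 0.01 by default; ceiling, with ties at the
cutoff broken by lexicographic pair id so selection is deterministic).
Each focal protein's occurrence count O among the top pairs is compared to
the even-share expectation E = T/K. The signed fold change is O/E when
O ≥ E and −(E/O) otherwise — never in (−1, 1), +1 at equality, −∞ flagged
when O = 0. Significance per protein is a 1-df chi-squared goodness-of-fit
of (O, T−O) against (E, T−E) with no continuity and no multiple-testing
correction (per-protein raw p-values). A pair whose two members are both
focal increments both proteins' counts by default (`double_count=False`
switches to first-member-only), so ΣO can exceed T while E stays T/K.
With T = 5,685 and K = 30 this arithmetic gives E = 189.5 and folds
+2.91 (O = 552), +2.78 (O = 526), and −23.69 (O = 8); published analyses
of this design print −23.68 for the last case, consistent with a top-set
size differing by a couple of values from ⌈0.01·N⌉.

## Complex benchmark

Real complexes (size ≥ 3) are scored by mean pairwise integrated ERC.
"Representation-matched" null complexes draw their sizes from the real
size distribution and their genes with probability proportional to each
gene's frequency of complex membership (Gumbel top-k weighted sampling
without replacement; uniform sampling available as a sensitivity switch).
Empirical p is the proportion of null complexes in the same
*effective-size* stratum (number of member genes actually present in the
matrix — ortholog missingness shrinks sets) with mean ≥ observed; one
shared null pool is stratified by size rather than simulating per size.
Benjamini–Hochberg q-values (statsmodels step-up) flag significance at
FDR 5%. Discriminative power is summarized as precision–recall of ranking
real vs null complexes by mean score, normalized to the precision at 100%
recall (the prevalence), i.e. fold change in precision; the call-everything
endpoint is appended to the curve so fold change is exactly 1 at recall 1.

## Synthetic data generator

The generator emulates the *structure* the method assumes — several
independent clades, a genes × branches length table per clade, modules of
genes with correlated per-branch deviations — not sequence evolution.
Per clade, a random rooted binary topology (random joins) gets master
lengths exp(Normal(ln 0.05, 0.5²)); gene g's lengths are
L[g,b] = A_b · s_g · exp(σ·d_g[b]) with ln s_g ~ Normal(0, gene_scale_sd²)
and d_g[b] = √ρ·f_m[b] + √(1−ρ)·e_g[b], the module factor f drawn fresh
per clade (clade-wise covariation, matching the premise that each clade
dataset is independent evidence). The target Pearson correlation ρ is
exact on the log scale the RER uses. Defaults: species per clade
(62, 39, 22, 18, 17), mirroring the five clade datasets the pipeline
targets; σ = 0.3 and gene_scale_sd = 0.3 (moderate rate dispersion —
log-deviations of ~30% keep branch lengths within the realistic
0.01–0.3 substitutions/site range); missing_prob = 0.15 per gene per
clade, emulating ortholog absence as whole-row dropout (1:1 orthologs are
not required in every clade in real datasets; per-branch missingness is
available but off by default). All randomness derives from one seed;
identical configs are byte-identical.

What the generator does *not* model — and hence what passing tests do not
establish about real data: phylogenetic autocorrelation of deviations
along the tree, branch-length estimation error from finite alignments,
alignment and ortholog-calling artifacts, heavy-tailed rate shifts, or
correlation structure between modules. Calibration results (uniform null
p-values, standard-normal clade z) say the statistics are internally
consistent, not that real branch-length data meet the model's assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so each
statistical property has clear resolution while the whole suite stays
fast: null calibration uses 500 genes × 5 clades of ~50 branches
(≈125,000 pairs; z SD checked on 5,000 sampled pairs per clade, KS
uniformity on 200 group tests of 400 permutations each); module recovery
uses a 10-gene ρ = 0.6 module in a 310-gene universe at 10,000
permutations over 10 seeds; the benchmark comparison uses 25 four-gene
ρ = 0.4 modules across five 10-species clades with 1,000 null complexes —
small clades deliberately underpower any single clade so the value of
integration is visible. Ties in top-quantile selection are broken
lexicographically; r is clamped at 1−1e-6 before atanh; empirical-p floors
are never reported as 0; BH q-values are order-invariant.

## Known limitations

- The integrated sum is not comparable across pairs observed in different
  numbers of clades without accounting for the √k null SD; consumers who
  need cross-pair comparability should filter to a common clade set or
  use the per-clade components stored with each pair.
- The master profile is estimated from the input gene set; analyses of
  small curated tables (hundreds of genes) are fine, but a focal module
  should not dominate the table.
- The permutation universe is the scored-gene universe of the supplied
  matrix; results are conditional on that universe, as in any
  proteome-wide permutation design.
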