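# Methods

This note documents the models, parameter choices, and numerical decisions
behind `xsci`, and what the synthetic-data experiments do and do not show.

## Study design being modeled

The pipeline targets a four-study, three-species comparison of the early
subacute (3/4 days post-injury) spinal-cord-injury response: two rat
microarray studies (clip compression, 4 injured / 4 sham; transection,
3 / 3), one mouse study (hemisection, 3 / 3), and one axolotl study
(transection, 3 / 3). All matrices are assumed to be RMA/gcRMA-style log2
intensities; no normalization is performed. The mouse is the reference
organism for ortholog harmonization; the axolotl annotation maps to human
symbols and reaches mouse through a second hop, taking the rank-1 candidate
at each hop.

## Differential expression

The two-group contrast per probeset uses the empirical-Bayes moderated t.
The hyperparameters (d0, s0²) are fitted by moment matching on z = log s²:
with e = z − ψ(d/2) + log(d/2), the excess of Var(e) (computed with the
n−1 denominator) over the sampling term ψ′(d/2) equals ψ′(d0/2), inverted
by Newton iteration on the trigamma function (starting point x = 0.5 + 1/y,
with asymptotic shortcuts outside [1e−6, 1e7]). Zero-variance probesets are
excluded from the fit; if *all* variances are zero the input is degenerate
and rejected. A non-positive excess means the observed variances are no more
dispersed than sampling alone predicts; the fit then uses the common pooled
variance s0² = exp(mean e) for every probeset with normal-reference
p-values (d0 = ∞), and logs the fallback. This happens routinely — and
harmlessly — when the generator's noise model is exactly homoskedastic.

Confidence intervals (95%, two-sided) use the moderated standard error and
d0 + d degrees of freedom: the moderated scale is the one the statistic is
referred to, so the interval and the p-value are mutually consistent.
Probesets without a gene annotation are dropped before collapsing; the
collapsing winner is the probeset with the highest mean expression across
all samples, ties resolved by smallest probeset id.

The whole fit is cross-checked in the test suite against the Bioconductor
reference implementation (run through `Rscript`) to ~1e−9 on hyperparameters,
t statistics, and p-values.

## Concordance classification

Two gates apply in order: presence of the reference ortholog in every
*species*, then significance (BH-adjusted p ≤ α, default 0.05) in every
*study*. "Consistent direction across three species" is read as all four
studies sharing one sign — the only reading under which the worked sign
cases are well defined; rat-internal disagreement yields `other`, as does
any exactly-zero fold-change (no direction). When two source genes resolve
to the same reference gene within one study, the smaller adjusted p
represents it (ties by source id); each collision is logged. The class
counts always satisfy n_consistent + n_opposite + n_other = n_significant;
the identity is asserted on every run.

## Enrichment

Standard over-representation: p = P(X ≥ k) for X ~ Hypergeometric(N, K, n),
sets intersected with the universe before testing, BH adjustment across the
sets of one namespace, default significance filter p_adj ≤ 0.05, and
ES = −log10(p_adj) (p_adj = 0 clamped to the smallest positive float,
logged). BH is used for set-level adjustment throughout — the pipeline does
not reproduce proprietary web-service corrections; the deviation is visible
in the output metadata simply because `p_adj` is documented as BH. The
default universe in the pipeline is the set of orthologs present in all
species after mapping — the background actually tested — since enrichment
against a larger, untested background would overstate significance.

## Conservation

Percent identity is defined on a *given* alignment: identical columns over
columns where neither member has a gap (internal and terminal gaps treated
alike). Published identities derived from local alignments (BLAST HSPs) are
therefore matched only approximately, by design. Poisson-corrected distances
use pairwise deletion — columns with a gap or `X` in either member are
removed per pair — then d = −ln(1 − p); p ≥ 1 has no finite distance and is
an error, not a clamp.

Neighbor joining follows the Saitou–Nei agglomeration with the standard
branch-length and distance-update formulas; the remaining three clusters are
resolved by the three-point formulas into a trifurcating (unrooted) root.
Ties in Q are broken by the lexicographically smallest taxon pair, internal
clusters represented by their smallest leaf name, so output is deterministic.
Negative branch lengths are clamped to zero with the deficit logged. On
additive matrices the tree reproduces all pairwise path lengths to 1e−9
(tested), and random-matrix topologies agree with an independent NJ
implementation.

Heatmap orderings: species columns by average-linkage hierarchical
clustering on 1 − cosine; gene rows by spherical k-means (rows L2-normalized,
centroids = normalized means, inertia = Σ(1 − cos)), default k = 4, 10
seeded restarts keeping the best inertia. Empty clusters are re-seeded at
the worst-fit row. All-zero rows have no direction under cosine and get the
sentinel label −1 (logged); an all-zero column is an error.

## Interactome

Edges are undirected; self-loops are dropped and duplicate undirected edges
collapsed to their maximum confidence at read time (both logged). The
confidence cut-off keeps edges with confidence ≥ 0.4 by default — the
"medium confidence" convention of the source database. After restricting to
the query genes, degree-0 nodes are removed and the remaining nodes ordered
by descending degree, ties lexicographic (the degree-sorted circle ordering).

## Imaging

Area fraction = proportion of pixels at or above threshold in a
single-channel image. The default threshold is Otsu's method — deterministic
and parameter-free — with a numeric override; a constant image has no Otsu
threshold and returns fraction 0. The group × region analysis is a
fixed-effects two-way ANOVA; unbalanced designs use Type II sums of squares.
Per-region group contrasts share the ANOVA residual mean square and its
degrees of freedom (the pooled-error convention of Holm–Šídák-after-ANOVA
in common GraphPad-style workflows), then adjust by the Holm–Šídák
step-down: ascending p, adj_i = 1 − (1 − p_i)^(m−i+1), running-max
monotonicity, cap at 1.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the real studies: per-study
probeset × sample log2 matrices (1–3 probesets per gene, one per gene with
a +1.5 elevated baseline so the collapsing rule has a deterministic winner),
ranked ortholog tables with a salamander→human→mouse chain and independent
5% per-hop dropout plus occasional rank-2 decoys, planted GMT sets covering
80% of each truth class padded with null genes, gap-free alignments evolved
by per-site Poisson substitution counts with uniform different-residue
jumps, interaction edge lists with a high-confidence planted hub module,
and two-level images with an exact planted foreground count.

Defaults are the study conditions the pipeline is exercised under: 500
genes, 10% planted consistent and 10% planted opposite, effect 2.0 log2
units against i.i.d. Gaussian noise of sd 0.5 (the standard assumption for
post-RMA log2 intensities), baselines uniform on [5, 9]. The planted-recovery
experiment runs all four studies at 4 samples/arm with ortholog dropout set
to 0, because dropout removes genes from the three-species intersection
before classification is even possible and is exercised separately by the
mapping tests.

Passing these tests shows the machinery is correct under its own model. It
does *not* show robustness to what real microarray data adds: batch and
platform effects, heteroskedastic and correlated noise, mean–variance
trends, annotation errors, paralog confusion in ortholog tables, alignment
uncertainty, or staining artifacts. The published headline counts
(198 significant orthologs partitioning 61/119/18) require the original
GEO accessions and are reproduced structurally, not numerically: the
partition identity, the exhaustive 16-sign-pattern fixture (2/2/12), and
planted-count recovery within ±10% stand in for them. Enrichment-score
arithmetic on the published adjusted p-values is reproduced exactly
(to two decimals); the one published pair whose ES does not equal
−log10(p_adj) is treated as a typo and excluded.

## Problem sizes

Simulation-based tests use 100–500 genes, 2–4 studies, 200–300 ANOVA null
replicates, 5000-site alignments over 20 seeds, and 100×100–200×200 images;
the full suite runs in well under a minute and the acceptance script in a
few seconds.
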