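# Methods

## p-distance and gap policy

For two aligned protein sequences the p-distance is p = n_diff / m, where m
counts the comparable sites and n_diff those comparable sites at which the
residues differ. Under the default **pairwise deletion**, a site is
comparable for a pair iff both sequences carry one of the 20 standard amino
acids there; gaps (`-`) and undetermined residues (`X`) are excluded per
pair. **Complete deletion** (optional) first removes every column containing
any gap/X in any sequence, then compares all pairs on the surviving columns.
Pairwise deletion is the default because it keeps the maximal information
per pair in raggedly aligned families; `X` is treated as missing because a
p-distance is defined over determined residues. A pair with m = 0 has an
*undefined* distance: it is flagged (NaN plus a flagged-pair list), never
imputed, and excluded from averages with a logged warning. Tree building
refuses undefined pairs outright.

## Per-clan diversity summaries

Within a clan with members i = 1..n (n ≥ 2), each member's observation is
its average p-distance to the other n − 1 members,
d_i = mean_{j≠i} p(i, j). The clan summary is the mean and sample SD
(n − 1 denominator) of the d_i. The clan mean of the d_i equals the mean of
all within-clan off-diagonal pairwise distances, so the summary is a
faithful compression of the pairwise structure. Clans with n < 2 are
reported with blank statistics ("not available") so each rank still
partitions the dataset. Two clans are compared by a two-sample t test from
summary statistics; Welch with Satterthwaite degrees of freedom is the
default, the pooled-variance variant is available for comparison with older
analyses that assumed equal variances.

## Variance partitioning (model II ANOVA, unequal sizes)

At a taxonomy node whose children are k ≥ 2 clans, the observations are the
per-sequence averages d_i computed **within the node's member set**
(node-local; a flag switches to raw pairwise distances as observations, but
those are non-independent — each sequence enters n − 1 pairs — so the
per-sequence unit is the default and the pairwise unit is provided only for
sensitivity analysis). The one-way random-effects decomposition gives
SS_among = Σ n_i (ȳ_i − ȳ)² on k − 1 df and SS_within on N − k df; the
unequal-size coefficient n0 = (N − Σ n_i²/N)/(k − 1) converts the mean
squares into components σ²_W = MS_within and
σ²_A = max(0, (MS_among − MS_within)/n0). The percentage split uses
σ²_A + σ²_W as denominator. Design notes:

- Negative σ²_A estimates are truncated to zero (standard practice for
  variance components); consequently the *mean* inter-clan share is inflated
  under the null while the *median* stays near zero — null calibration is
  therefore stated on the median.
- Singleton clans are included: they contribute to the among-clan sum of
  squares but no within-clan degrees of freedom. A node is skipped only
  when k < 2, N ≤ k, or every clan is a singleton; each skipped node is
  reported with its reason rather than silently dropped.
- With exactly two clans of *equal* size and equal internal diversity the
  clan means of the d_i coincide by symmetry, so the per-sequence
  observation unit carries no between-clan signal in that degenerate
  balanced case; with unequal sizes — the regime this estimator is built
  for, and the norm in taxonomic data — the asymmetry of cross-clan pair
  counts transmits the signal (verified by simulation in the test suite).
- Percentages are descriptive; no F test is attached, as the quantity of
  interest is the share of variance crossing the boundary, not a null
  hypothesis about it.

In the taxonomy walk, prokaryote-style lineages lacking a kingdom get a
placeholder kingdom node named after the superkingdom, so the
superkingdom→phylum bifurcation appears at that placeholder node and every
lineage path keeps eight levels.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration: minimise
Q(i, j) = (r − 2) d(i, j) − R_i − R_j, join with
l_i = d(i,j)/2 + (R_i − R_j)/(2(r − 2)), reduce with
d(u, k) = (d(i,k) + d(j,k) − d(i,j))/2, and resolve the final three nodes
exactly. Ties in Q are broken by the lowest (row, col) pair in the current
ordering (input order, new nodes appended), making runs deterministic. A
negative branch length is clamped to zero and its deficit moved to the
sister edge, preserving the joined pair's path length. On additive matrices
the output tree's path lengths reproduce the input exactly (property-tested
to 1e-9 over random trees, n ≤ 10).

Supports: alignment columns are resampled with replacement B times (default
1000 for publication-scale runs; the bundled pipelines default to 100 to
keep interactive runs fast), the tree is rebuilt per replicate under the
same gap policy, and each internal edge of the main tree receives the
fraction of retained replicates containing the same bipartition. Replicates
that produce an undefined pair are dropped and counted. Trees serialize to
Newick with supports as internal-node labels; reading back reproduces
topology, lengths and supports.

## Simulator

Families are generated over a configurable taxonomy: per-rank branching
counts (fixed or ranges, giving the uneven clan sizes real data shows) down
to organisms, one aligned sequence per organism. Sequences evolve from an
i.i.d.-uniform root under the 20-state equal-rates model; a branch with d
expected substitutions per site changes each site with probability
(19/20)(1 − e^(−20d/19)), the exact transition kernel, so the expected
pairwise p-distance between two leaves is that closed form evaluated at
their total path length — the calibration oracle used in the tests. Default
per-rank divergences (phylum 0.25, class 0.15, order 0.10, family 0.10,
genus 0.08, leaf 0.15 substitutions/site) put clan-mean p-distances roughly
in the 0.3–0.8 band observed for deep protein families, with the default
sequence length of 600 residues matching a typical amylase alignment. One
seed drives taxonomy sampling, evolution, transfer placement and gap
masking.

Horizontal transfer is modelled as whole-sequence replacement: a recipient
leaf's sequence is replaced by a copy of a donor from a different clan at a
chosen rank, evolved a further 0.02 substitutions/site. Recipients are
distinct and donors are never previously-modified sequences, so every
logged event remains verifiable on the final alignment. This is deliberately
crude — real transfers are often partial and ancient — but it produces the
two signatures the analysis reads: mixed-clan clusters in the tree and a
depressed inter-clan variance share at the affected node (the latter is a
tested monotone property).

Gaps are introduced separately by masking each residue independently with a
given probability, so a pair's expected comparable-site count is
L(1 − fraction)². The simulator emulates neither indel evolution, rate
heterogeneity across sites, selection, nor alignment error; passing tests
on synthetic data therefore validate the statistical machinery, not the
adequacy of any alignment of real sequences.

## Numerical and scale choices

Distances are exact rational arithmetic in double precision (counts divided
once), and the ANOVA agrees with a naive double-loop oracle to 1e-10.
Monte-Carlo checks use 3 standard errors of the estimate. Test and
acceptance problem sizes — families of tens of sequences, lengths 300–2000,
50 calibration replicates, 1000 null replicates, bootstrap 10–100 — were
chosen as the smallest sizes at which the Monte-Carlo error bands are
meaningfully narrow; every stage scales to thousands of sequences, where
the O(n²L) distance matrix and O(n³) NJ dominate.

## Limitations

- The inter-clan share is a descriptive proxy for horizontal-transfer
  propensity; it also responds to unequal sampling of clans, rate
  variation between clans, and taxonomy errors.
- p-distances saturate (asymptote 0.95 under the 20-state model); no
  model-corrected distances (Poisson, JTT) are offered, since the analysis
  is defined on raw p-distances.
- NJ with clamped branches is a heuristic on non-additive matrices; exact
  topology agreement with other NJ implementations (which differ in
  tie-breaks and corrections) is not guaranteed — bipartition-level
  comparison is the meaningful contract.
- The completeness filter's kingdom rule (required only for eukaryotes by
  default) matches how public databases document prokaryotes; a strictness
  flag exposes both behaviors because curation conventions vary.
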