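# clandiv

Taxonomic diversity analysis of aligned protein families: per-clan pairwise
p-distance summaries, inter-/intra-clan variance partitioning by
unequal-size model II ANOVA along the taxonomic lineage, and neighbor-joining
trees with bootstrap supports.

## The problem

Large protein families (amylases are the motivating case) span archaea,
bacteria and eukaryota, and their evolution mixes vertical descent with
horizontal gene transfer. Given a multiple sequence alignment and a
per-sequence taxonomic lineage (superkingdom → kingdom → phylum → class →
order → family → genus → organism), three questions arise for anyone who
wants to engineer or transplant a family member:

1. **How diverse is each taxonomic group?** For every clan (a named taxon at
   some rank) we compute each member's *average pairwise p-distance* — the
   mean proportion of differing amino-acid sites between that sequence and
   the other clan members, with per-pair (pairwise-deletion) gap handling —
   and summarise the clan as mean ± SD with its n.
2. **Does diversity accumulate within or across taxonomic boundaries?** At
   every bifurcation of the taxonomy the per-sequence averages are
   partitioned by one-way random-effects (model II) ANOVA with unequal group
   sizes: with k clans of sizes n_i, N = Σ n_i,

       n0    = (N − Σ n_i²/N) / (k − 1)
       σ²_W  = MS_within
       σ²_A  = max(0, (MS_among − MS_within) / n0)
       inter-clan % = 100 σ²_A / (σ²_A + σ²_W)

   A large inter-clan share at a node flags diversity crossing the taxonomic
   boundary — the statistical signature of horizontal transfer — while a
   large intra-clan share indicates ordinary vertical descent.
3. **What does the gene tree look like?** Neighbor joining (Saitou–Nei) on
   the p-distance matrix, with supports from resampling alignment columns
   with replacement, written as Newick.

A calibrated simulator generates aligned families over a known taxonomy
(20-state equal-rates substitution model with closed-form expected
p-distance, optional cross-clan transfer events), so every stage is testable
against ground truth without downloading anything.

## Worked example

The variance partition on five observations in two clans, {1, 2, 3} vs
{7, 8}:

```python
>>> from clandiv import ClanVarianceModel
>>> res = ClanVarianceModel([1, 2, 3, 7, 8], ["a", "a", "a", "b", "b"]).fit()
>>> print(res.summary())
Inter-/intra-clan variance partition (model II ANOVA)
========================================================
clans (k): 2    observations (N): 5
clan sizes: [3, 2]
source          df            SS            MS
among            1     36.300000     36.300000
within           3      2.500000      0.833333
n0 (effective clan size): 2.4000
sigma2 among: 14.777778    sigma2 within: 0.833333
inter-clan: 94.66 %    intra-clan: 5.34 %
```

The two clan means (2 and 7.5) differ far more than the within-clan spread,
so almost 95 % of the variance lies *between* the clans: n0 = 2.4 converts
the among-clan mean square (36.3) into the among-clan variance component
σ²_A = 14.78, against σ²_W = 0.83 within clans.

End-to-end on a synthetic family:

```sh
clandiv simulate --seed 1 --out demo/
clandiv run --alignment demo/family.fasta --lineages demo/lineages.tsv \
    --bootstrap 100 --seed 1 --out demo/run/
```

`demo/run/` then contains `pdistance.phylip.tsv` (the distance matrix),
`rank_summary.tsv` (one row per clan and rank: n, mean_p, sd_p),
`variance_partition.tsv` (one row per taxonomy bifurcation: k, sizes, n0,
mean squares, σ²_A, inter/intra percentages, or the reason a node was
skipped), `tree.nwk` (NJ tree with supports) and `manifest.json` (stage
counts; byte-identical across reruns with the same config and seed).

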