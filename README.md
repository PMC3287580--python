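# svdtax

Alignment-free grouping of species by protein content.

`svdtax` turns each species' concatenated protein sequences into an
amino-acid **trigram** composition vector (20³ = 8000 overlapping 3-mers),
reduces the resulting 8000 × n matrix *A* with a truncated singular value
decomposition, clusters species by Euclidean distance in the reduced space,
and scores every clustering against the 14-rank Linnaean taxonomy. It is
aimed at comparative genomics users who want a fast, assembly- and
alignment-free view of relatedness across dozens of proteomes (the original
use case: 13 concatenated mitochondrial gene families per vertebrate
species), plus a defensible, automatic way to choose the two tuning knobs
every such pipeline hides — the SVD rank and the clustering granularity.

## Method

Given the trigram count matrix *A* (trigrams × species):

1. **SVD reduction.** *A* = *U*Σ*V*ᵀ; keeping the *k* strongest singular
   values gives the reduced species representation
   *D_k* = Σ_k *V_k*ᵀ (*k* coordinates per species, the
   latent-semantic-indexing document embedding). At full numerical rank the
   Euclidean distances between *D_k* columns equal those between raw
   columns of *A*; truncation removes the weakest directions ("noise") and
   can only shrink distances.
2. **ASAP clustering.** A single-pass threshold clusterer: take the first
   remaining species as pivot, absorb every species at distance < *d*,
   remove the cluster, repeat. *d* = 0 gives n singletons; *d* above the
   maximum distance gives one cluster.
3. **Linnaean quality.** Each cluster scores
   cLtlf = |cluster| × (shared Linnaean levels), where shared levels is the
   longest common lineage prefix over the 14 canonical ranks
   (Superregnum → Species; singletons score 13 by convention). Partition
   summaries: ΣcLtlf, mean, sample σ, **Lcq** = ΣcLtlf/σ, and the median.
4. **kdc search.** For each rank *k* on an EDRD-spaced grid
   (EDRD ≈ n/25), derive the thresholds *d* realizing each target cluster
   count *c*, score every (k, d, c) triad, and gate on whether the
   **positive control group** (a set of species known to belong together,
   e.g. a class) lands integrally and alone in one cluster. If no triad
   isolates it, species stranded in singleton clusters are dropped and the
   search recurses. Valid triads are ranked ("Finalize") by median cLtlf,
   with a secondary control group taking precedence when configured.
5. **Trees.** Any distance matrix can be written as a PHYLIP square matrix
   or summarized as a neighbor-joining Newick tree.

## Worked example

Generate a synthetic dataset of 4 planted clades × 5 species (protein
length 2000, clade 1 = positive control, clade 2 = secondary control) and
run the full search:

```
$ svdtax simulate --seed 1 --out-dir demo
wrote 20 species fixture to demo

$ svdtax search --fasta demo/species.fasta --taxonomy demo/taxonomy.tsv \
    --control demo/control.txt --secondary-control demo/secondary_control.txt \
    --out-dir demo_run
best kdc: k=3 d=13.5033 c=4 median cLtlf=50.00 (depth 0)

$ head -3 demo_run/ranking.tsv | cut -f1-5,12-15
rank_position  clusters    k    d        N   median_cltlf  n_singletons  control_isolated  secondary_isolated
1              04clusters  K03  13.5033  4   50.00         0             True              True
2              04clusters  K04  28.7224  4   50.00         0             True              True
```

Reading this: already at rank 3 a threshold of ≈13.5 splits the 20 species
into exactly the 4 planted clades (`partition_01_k3_c4.tsv` lists the
members). Each cluster holds 5 species sharing 10 Linnaean levels, so every
per-cluster cLtlf is 5 × 10 = 50, the median is 50.00, there are no
singleton clusters, and both control clades are isolated — the
configuration the search should prefer. A tree of the same space:

```
$ svdtax tree --fasta demo/species.fasta --k 3 --out demo.nwk
wrote Newick tree for 20 taxa to demo.nwk
```

Other subcommands: `featurize` (FASTA → MatrixMarket trigram matrix),
`reduce` (rank-k PHYLIP distances), `cluster` (one ASAP or k-means run),
`quality` (score any partition TSV against a taxonomy), `compare`
(reduced- vs full-rank comparison table for ASAP and k-means).

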