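# coliphagenet

Tools for cataloging prophages predicted in bacterial genome collections —
built around urinary *Escherichia coli* and its coliphages, but applicable to
any cohort of predicted prophage sequences with gene annotations.

Collections of bacterial genomes routinely harbour hundreds to thousands of
integrated phages (prophages). Making sense of such a catalog means answering
a handful of recurring questions: which prophages are related (and how do the
relationships organise into a network), how many distinct phage "species" are
present, what do the prophages carry (integrases, virulence factors,
antibiotic-resistance genes), how do they compare to phages from other body
sites, and — for phages that can be induced and grown — which bacterial
strains they lyse and which small phage cocktail covers the most strains.
`coliphagenet` implements that whole analysis chain as a library plus a CLI,
with a seeded synthetic-cohort generator so every stage is testable without
external databases.

## What it computes

**Gene-sharing network.** Genes from all prophages are grouped into homolog
families by all-vs-all Smith–Waterman scoring, a *minbit* filter
(score ÷ min(self-scores) ≥ 0.35) and Markov Clustering (inflation 2,
implemented from scratch). Membership pivots into a binary genome ×
gene-cluster presence/absence matrix *P* with row sums *l_i*, from which

    S = P·Pᵀ,   A_genome = sign(S),   A_gene = sign(Pᵀ·P)

give shared-gene counts and genome/gene adjacency. Each genome pair sharing
*s* gene clusters gets the normalised weight *w = s / (l₁·l₂)*; edges are
retained when *w > minw* (or, alternatively, when *s*/min(*l₁*, *l₂*) ≥ *f*),
and connected components of the retained graph are the catalog's phage groups.

**Species-level clustering.** Greedy incremental clustering of whole prophage
sequences at 80% identity with an 80% length-difference cutoff and word-length
4 prescreening, longest-first, with `.clstr`-style output and the longest
member as each cluster's representative.

**Annotation screens.** Threshold classifiers over tabular similarity hits:
taxonomy (query coverage > 50% and identity > 70%, best hit by bitscore),
virulence factors (identity ≥ 90% and ≥ 90% of the factor gene covered),
gut-phageome comparison tiers (match / full-coverage / identical), integrase
flagging by product-description substring, and tabulation of external
resistance-caller output.

**Host range.** Spot-assay replicate aggregation, per-phage host counts, 2×2
pairwise susceptibility tables, cocktail coverage (strains lysed by ≥ 1 phage
of a set) and exhaustive best-cocktail search. A worked-example lysis panel
(19 phages × 13 strains) and a 103-strain two-phage susceptibility table ship
with the package.

## Worked example

A three-family synthetic cohort (5 genomes per family, three single-gene
modules of 600 bp, 3% per-site divergence), pushed through the full chain:

```python
from coliphagenet import SimConfig, run_pipeline
from coliphagenet.cluster import cluster_summary

cfg = SimConfig(n_families=3, modules_per_family=3, genes_per_module=1,
                genomes_per_family=5, mosaicism_rate=0.0, mutation_rate=0.03,
                gene_length=600, seed=1)
res = run_pipeline(cfg, minw=0.0)
print("gene clusters:", len(set(res.gene_assignment.values())))
print("network components:", res.network.n_components)
cs = cluster_summary(res.clusters)
print("species clusters:", cs.n_clusters, "singletons:", cs.n_singletons)
```

prints

```
gene clusters: 9
network components: 3
species clusters: 3 singletons: 0
```

— the 45 gene copies collapse into the 9 planted ancestral gene families, the
genome network splits into exactly the 3 planted phage families at *minw* = 0,
and species-level clustering recovers the same 3 families (no singletons,
since every genome has kin). The same stages are available as CLI
subcommands:

```bash
coliphagenet simulate --outdir sim --seed 1 --genes-per-module 1 --mosaicism-rate 0
coliphagenet pangenome --genes sim/genes.fasta --outdir pan
coliphagenet network --gene-clusters pan/gene_clusters.tsv \
    --genes-table sim/genes.tsv --outdir net --minw 0
coliphagenet cluster --fasta sim/genomes.fasta --outdir clust
coliphagenet report --simdir sim --outdir rep
```

For the host-range side:

```python
from coliphagenet.hostrange import (load_pair_counts, matrix_from_pair_counts,
                                    cocktail_coverage)
from coliphagenet.report import percent

pt = load_pair_counts()                       # T2/N4 vs 103 urinary strains
m = matrix_from_pair_counts(pt)
n, _ = cocktail_coverage(m, ["T2", "N4"])
print(n, percent(n, pt.n_total, 1)[1])        # -> 86 83.5%
```

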