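# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, and what the synthetic cohorts do and do not establish
about behaviour on real prophage catalogs.

## Synthetic cohorts

The generator plants a fully known family structure. A cohort has
`n_families` unrelated phage families; each family owns
`modules_per_family` gene modules of `genes_per_module` ancestral genes,
drawn uniformly over {A,C,G,T} at `gene_length` bp. Module 0 is the core
module, present in every genome of its family; each accessory module is
carried independently with probability `1 − mosaicism_rate`. Every gene copy
is its ancestor mutated i.i.d. per site at `mutation_rate`; a mutated site
always changes base (uniform over the other three), so the number of
mismatches to the ancestor is exactly Binomial(L, µ) and two copies of one
ancestor match at a site with probability (1−µ)² + µ²/3 (≈ 0.94 at µ = 0.03,
≈ 0.81 at µ = 0.10). Genomes are the concatenation of their gene copies in
module order, all on the + strand (the network operates on gene content, not
orientation); coordinates are 0-based half-open throughout. The first core
gene of every genome carries the product string "site-specific integrase" so
the integrase screen has a planted positive; all other products are
"hypothetical protein".

Defaults (3 families × 3 modules × 2 genes × 5 genomes, µ = 0.03, mosaicism
0.1, 600 bp genes) describe a desk-scale cohort in which between-family
identity sits at the random-DNA floor (~25% per site) and within-family
identity is high — the planted signal all recovery tests use. One seeded
`numpy` generator drives all draws (ancestors and genomes use separate
streams derived from the same seed, so regenerating one never perturbs the
other); identical configurations produce byte-identical outputs.

What the simulations do **not** emulate: real gene-length variation, codon
structure, horizontal transfer between families, sequencing or assembly
error, prophage-prediction noise, or partial/questionable prophages. Passing
recovery tests therefore demonstrates correctness of the algorithms under
clean planted signal, not robustness to the messiness of real catalogs.

Fabricated hit tables and spot matrices exist so the screening and
host-range stages are testable in isolation: hits are emitted in the
12-column tabular search convention extended with query coverage (col 13)
and subject coverage (col 14); spot matrices draw one Bernoulli(breadth)
call per phage–strain pair, copied across replicates unless per-replicate
noise is requested.

## Gene-family clustering (pan-genome stage)

Pairwise similarity is Smith–Waterman local alignment on nucleotide gene
sequences with match +5, mismatch −4, gap open −8, gap extend −2 (a gap of
length L costs 8 + 2(L−1)); the self score of a length-L sequence is then
exactly 5L. The scores are computed by Biopython's pairwise aligner; an
independently written full-DP implementation backs it in the test suite.
All-vs-all scoring is prescreened by shared 8-mers: at the divergence levels
simulated (µ ≤ 0.1 over ≥ 200 bp) truly homologous pairs share 8-mers with
overwhelming probability, so the prescreen only skips unrelated pairs.

The minbit statistic normalises each score by the smaller of the two self
scores, giving a similarity in [0, 1]; edges below 0.35 are dropped. The
threshold and the MCL inflation of 2 are the stage's two published-style
parameters; everything else is a numerical convention chosen here:
self-loops at the node's maximum incident weight (1.0 for isolated nodes),
column-stochastic normalisation, expansion as the matrix square, inflation
as elementwise square followed by renormalisation, pruning of entries below
1e−5, convergence when the largest entry change falls below 1e−6, and a cap
of 100 iterations (non-convergence warns and uses the last iterate —
unobserved in practice on these graph sizes). Clusters are read off
attractor-row supports; a node claimed by several attractors goes to the one
holding the largest mass, ties to the lowest node index, and cluster ids are
dense integers ordered by smallest member. Genes with no surviving edge are
singleton clusters — how unclustered genes were handled upstream of the
original network analyses is generally unstated, and the singleton
convention is the conservative choice (it can only split, never merge,
phage groups).

This stage operates on nucleotide genes rather than translated proteins:
it keeps the package dependency-free of annotation engines while preserving
the minbit semantics. On real data, amino-acid scoring would detect remoter
homology; nucleotide scoring is conservative in the same direction as the
singleton convention.

## Sharing network

*l_i* is defined as the number of distinct gene clusters in genome *i* (row
sum of P), not its bp length — "genome size" is ambiguous in gene-sharing
formulations, and the cluster-count reading keeps *w = s/(l₁·l₂)*
dimensionless and bounded by 1/max(l₁, l₂). The edge rule is strict
(*w > minw*); the alternative fraction rule (*s*/min(l₁, l₂) ≥ *f*,
inclusive) is exposed separately because "shares at least 30% of its genic
content" phrasings describe that statistic, not *w*, and the two are not
equivalent. Components come from union–find with labels canonicalised by
smallest member id, so output is invariant to edge-list order. Exports are
plain TSV edge/node tables and a SIF file loadable by network viewers.

## Species-level clustering

Greedy incremental clustering, longest-first (ties by id), first-fit: a
sequence joins the first cluster whose representative passes the length
ratio (shorter/longer ≥ 0.8), shares a 4-mer, and aligns at ≥ 80% identity;
otherwise it founds a new cluster. Representatives are therefore always the
longest member, and the canonical sort makes output independent of input
order.

Identity is defined against the shorter sequence: the shorter is aligned
semi-globally within the longer (end gaps on the longer are free) and
identity = 1 − d/len(shorter), where d is the edit distance of that
alignment (computed with edlib; an unbanded full-DP oracle verifies it in
tests). This definition was chosen over a banded match-counting DP because
the edit distance is unique across co-optimal alignments, which makes
oracle comparisons exact and the join decision reproducible; at the
thresholds used the two definitions agree to well under the 80% decision
boundary's width. For equal-length inputs the first argument plays the
query role. The `.clstr` output format prints member identities to two
decimals with the representative line ending in `*`.

## Screens

Thresholds follow each screen's stated rule exactly, including strictness:
taxonomy requires coverage strictly > 50 and identity strictly > 70 (a hit
at exactly 50.0 fails), VF and gut screens are inclusive (≥). "Query length
< 90% of the virulence-factor gene" is implemented as subject coverage
≥ 90% — the denominator named is the factor gene's length. The gut tiers
are nested by construction (identical ⊆ full-coverage ⊆ match) and each
prophage reports its strictest tier; the match tier keeps the ≥ 70% identity
threshold of the screen definition even though real comparisons tend to
exceed 80% whenever coverage passes. Among multiple qualifying taxonomy
hits the best hit wins by bitscore, then identity, then lexicographic
subject id (a consensus rule would be an alternative; best-hit is the
standard convention and is deterministic). Integrase flagging is a
case-insensitive substring test on product descriptions. All screens are
monotone in their thresholds and idempotent on their own output.

## Host range

Replicates (≥ 4 technical replicates in a typical spot assay) collapse to
one call per phage–strain pair; the default rule requires **every**
replicate to show complete lysis, the stricter of the two defensible
readings of a binary "completely lysed" score, with "any" selectable. Pair
tables count both/A-only/B-only/neither over a strain panel (the four cells
always sum to the panel size); cocktail coverage counts strains lysed by at
least one phage of the set; best-cocktail search is exhaustive over size-k
subsets with lexicographic tie-breaks — at panel scale (tens of phages)
exhaustive search is exact and instant, so no greedy set-cover
approximation is used.

The bundled panel fixtures encode a published-style worked example: a
19-phage × 13-strain qualitative lysis pattern (with strain phylotype and
source-group metadata) and a 103-strain two-phage susceptibility count
table. `matrix_from_pair_counts` expands count tables into explicit boolean
matrices with synthetic strain ids so matrix-level operations run on
count-only data.

## Reporting

Percentages are rounded half away from zero at the printed precision
(5/8 → "63%", not banker's "62%"); this reproduces the catalog-style
renderings such as 59.48% (1 807/3 038) and 83.5% (86/103) from their count
pairs. `catalog_summary` computes exact tallies with conservation checks
(class counts must sum to totals; screens may not reference unknown
prophages) and refuses to report otherwise.

## Problem sizes

Recovery checks run on 3 families × 5 genomes with three single-gene 600 bp
modules (45 genes, 15 genomes) at µ = 0.03 — large enough that within- and
between-family similarity distributions are fully separated, small enough
that every oracle (full DP, dense MCL iteration, brute-force cluster scan)
runs in seconds. The end-to-end fixture sets mosaicism to 0 so
within-family genome lengths are comparable; with heavy mosaicism the 80%
length-difference cutoff legitimately splits a family into length strata,
which is a property of the clustering definition, not an error. The
gene-family recovery score is the adjusted Rand index against the planted
ancestor labels, with one gene per module so module-level and
ancestor-level labels coincide (with several genes per module the recovered
partition is strictly finer than module labels by construction).

## Known limitations

* Nucleotide-space homology detection misses remote homologs that
  amino-acid scoring would find.
* The greedy clusterer is first-fit, so a sequence near two thresholds can
  join a different cluster than a best-fit rule would choose (the
  brute-force oracle applies the same rule, so tests pin the behaviour, not
  an optimum).
* MCL is run dense; catalogs beyond a few thousand genes per connected
  similarity block would want a sparse implementation.
* The screens consume externally produced hit tables; nothing here replaces
  a sequence search engine, and e-values are not computed.
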