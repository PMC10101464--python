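"""Gene-family (homolog) clustering: pairwise similarity, minbit, and MCL.

The pan-genome stage groups the genes of all prophages into homolog families,
which then become the columns of the genome × gene-cluster presence/absence
matrix. Three steps:

1. all-vs-all pairwise similarity — Smith–Waterman local alignment scores
   (match +5, mismatch −4, gap open −8, gap extend −2) on nucleotide gene
   sequences, with a shared 8-mer prescreen so unrelated pairs are skipped
   without alignment;
2. the minbit filter — each score is normalised by the smaller of the two
   self-alignment scores (``minbit = score / min(self_a, self_b)``, in [0, 1])
   and edges below the threshold (default 0.35) are discarded;
3. Markov Clustering (MCL) of the surviving similarity graph at inflation 2,
   implemented here directly: random-walk expansion (matrix power) alternating
   with inflation (elementwise power + column renormalisation) until the flow
   matrix is stable, clusters read off the attractor rows.

Genes left without any retained edge become singleton clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .errors import DataError, ValidationError
from .io import write_tsv

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 5, -4, -8, -2
PRESCREEN_K = 8

_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner(
            mode="local",
            match_score=MATCH,
            mismatch_score=MISMATCH,
            open_gap_score=GAP_OPEN,
            extend_gap_score=GAP_EXTEND,
        )
    return _aligner


def pair_score(seq_a: str, seq_b: str) -> float:
    """Smith–Waterman local alignment score (+5/−4, gaps −8 open −2 extend).

    The self score of a length-L sequence is exactly 5·L; the local-alignment
    floor is 0 for sequences with no positively scoring local match.
    """
    if not seq_a or not seq_b:
        raise ValidationError("pair_score requires non-empty sequences")
    return float(_get_aligner().score(seq_a, seq_b))


def self_score(seq: str) -> float:
    """Self-alignment score, 5·len by construction of the scoring scheme."""
    if not seq:
        raise ValidationError("self_score requires a non-empty sequence")
    return float(MATCH * len(seq))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def score_all_pairs(genes: dict[str, str], k: int = PRESCREEN_K) -> pd.DataFrame:
    """All-vs-all similarity edges with minbit, after a shared-k-mer prescreen.

    Returns a DataFrame (gene_a, gene_b, score, minbit) with gene_a < gene_b;
    pairs sharing no k-mer, or scoring 0, are omitted.
    """
    ids = sorted(genes)
    kmer_index: dict[str, list[int]] = {}
    for i, gid in enumerate(ids):
        for w in _kmers(genes[gid], k):
            kmer_index.setdefault(w, []).append(i)
    candidates: set[tuple[int, int]] = set()
    for members in kmer_index.values():
        if len(members) > 1:
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    candidates.add((members[x], members[y]))
    rows = []
    for i, j in sorted(candidates):
        a, b = ids[i], ids[j]
        s = pair_score(genes[a], genes[b])
        if s <= 0:
            continue
        mb = s / min(self_score(genes[a]), self_score(genes[b]))
        rows.append((a, b, s, mb))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "minbit"])


def minbit_filter(edges: pd.DataFrame, threshold: float = 0.35) -> pd.DataFrame:
    """Keep edges whose minbit (score over the smaller self score) >= threshold."""
    if "minbit" not in edges.columns:
        raise DataError("edges lack a minbit column; self scores unavailable")
    return edges[edges["minbit"] >= threshold].reset_index(drop=True)


@dataclass(frozen=True)
class MclParams:
    """Markov Clustering controls; inflation is the granularity knob."""

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("max_iter >= 1 and tol > 0 required")


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(
    nodes: list[str],
    edges: pd.DataFrame,
    params: MclParams = MclParams(),
) -> dict[str, int]:
    """Partition `nodes` by Markov Clustering of the weighted similarity graph.

    Self-loops are added with weight equal to the node's maximum incident edge
    weight (1.0 for isolated nodes), the matrix is column-normalised, and
    expansion/inflation/pruning are iterated until the largest entry change
    falls below ``tol``. Clusters are the supports of attractor rows; a node
    claimed by several attractors goes to the one holding the largest mass,
    ties to the lowest node index. Cluster ids are dense integers from 0,
    ordered by each cluster's smallest node index.
    """
    n = len(nodes)
    if n == 0:
        return {}
    index = {node: i for i, node in enumerate(nodes)}
    if len(index) != n:
        raise DataError("duplicate node ids")
    m = np.zeros((n, n))
    if len(edges):
        weight_col = "weight" if "weight" in edges.columns else "score"
        for a, b, w in edges[["gene_a", "gene_b", weight_col]].itertuples(index=False):
            if w < 0:
                raise ValidationError(f"negative edge weight {w} on ({a}, {b})")
            i, j = index[a], index[b]
            m[i, j] = m[j, i] = max(m[i, j], float(w))
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m = _normalize_columns(m)

    converged = False
    for _ in range(params.max_iter):
        nxt = np.linalg.matrix_power(m, params.expansion)
        nxt = nxt ** params.inflation
        nxt[nxt < params.prune_threshold] = 0.0
        nxt = _normalize_columns(nxt)
        diff = np.abs(nxt - m).max()
        m = nxt
        if diff < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iter} iterations; "
            "using last iterate", RuntimeWarning,
        )

    attractors = [i for i in range(n) if m[i, i] > 0]
    owner = np.full(n, -1, dtype=int)
    for j in range(n):
        masses = [(m[i, j], -i) for i in attractors if m[i, j] > 0]
        if masses:
            owner[j] = -max(masses)[1]
    # nodes with no attractor mass (pre-convergence corner): follow argmax row
    for j in range(n):
        if owner[j] < 0:
            i = int(np.argmax(m[:, j]))
            owner[j] = owner[i] if owner[i] >= 0 else j
    clusters: dict[int, list[int]] = {}
    for j in range(n):
        clusters.setdefault(int(owner[j]), []).append(j)
    ordered = sorted(clusters.values(), key=min)
    out: dict[str, int] = {}
    for cid, members in enumerate(ordered):
        for j in members:
            out[nodes[j]] = cid
    return out


def cluster_genes(
    genes: dict[str, str],
    params: MclParams = MclParams(),
    minbit: float = 0.35,
    prescreen_k: int = PRESCREEN_K,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Full gene-family stage: score, minbit-filter, MCL. Returns (assignment, edges)."""
    edges = score_all_pairs(genes, k=prescreen_k)
    kept = minbit_filter(edges, minbit)
    assignment = mcl_cluster(sorted(genes), kept, params)
    return assignment, edges


def write_outputs(assignment: dict[str, int], edges: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(
        pd.DataFrame(sorted(assignment.items()), columns=["gene_id", "cluster_id"]),
        outdir / "gene_clusters.tsv",
    )
    write_tsv(edges, outdir / "edges.tsv")
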