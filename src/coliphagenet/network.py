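"""Genome- and gene-level sharing networks from gene-cluster membership.

Gene-cluster assignments are pivoted into a binary genome × gene-cluster
presence/absence matrix P (rows: genomes, columns: homolog families; row sum
l_i is the size of genome i in gene clusters). The genome network follows from

    S = P · Pᵀ          (shared gene-cluster counts)
    A_genome = sign(S)  (two genomes connected iff they share any cluster)

and symmetrically ``A_gene = sign(Pᵀ · P)`` for gene-cluster co-residence.
Each genome edge carries the normalised weight

    w = s / (l_a · l_b)

and an edge survives only if ``w > minw`` (strict). An alternative edge rule
keeps pairs sharing at least a fraction f of the smaller genome's clusters
(``s / min(l_a, l_b) >= f``); both are exposed because "shared genic content"
thresholds are often stated that way. Connected components of the retained
graph are the catalog's phage groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import write_tsv

EDGE_COLUMNS = ["genome_a", "genome_b", "s", "w", "l_a", "l_b"]


@dataclass
class PresenceMatrix:
    """Binary genomes × gene-cluster matrix with genome sizes l_i."""

    matrix: pd.DataFrame  # index: genome ids, columns: cluster ids, values {0,1}

    def __post_init__(self):
        values = self.matrix.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("presence matrix entries must be binary")
        # all-zero columns carry no signal and are dropped
        keep = self.matrix.columns[self.matrix.sum(axis=0) > 0]
        self.matrix = self.matrix[keep]

    @property
    def genomes(self) -> list:
        return list(self.matrix.index)

    @property
    def l(self) -> pd.Series:
        """Genome sizes: number of distinct gene clusters per genome."""
        return self.matrix.sum(axis=1)


def build_presence_matrix(
    assignments: dict[str, int], gene_to_genome: dict[str, str]
) -> PresenceMatrix:
    """Pivot gene -> cluster assignments into the P matrix (multiplicity -> 1)."""
    if not assignments:
        raise DataError("empty gene-cluster assignment")
    missing = [g for g in assignments if g not in gene_to_genome]
    if missing:
        raise DataError(f"genes with unknown genome: {missing[:5]}")
    df = pd.DataFrame(
        {
            "genome": [gene_to_genome[g] for g in assignments],
            "cluster": list(assignments.values()),
        }
    )
    mat = (
        pd.crosstab(df["genome"], df["cluster"])
        .clip(upper=1)
        .astype(np.int8)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    mat.index.name = None
    mat.columns.name = None
    return PresenceMatrix(mat)


def genome_adjacency(p: PresenceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-cluster counts S = P·Pᵀ and unweighted adjacency sign(S), diag zeroed."""
    m = p.matrix.to_numpy()
    s = m @ m.T
    adj = np.sign(s)
    np.fill_diagonal(adj, 0)
    ids = p.genomes
    return (
        pd.DataFrame(s, index=ids, columns=ids),
        pd.DataFrame(adj, index=ids, columns=ids),
    )


def gene_adjacency(p: PresenceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Co-residence counts Pᵀ·P and adjacency sign(Pᵀ·P) over gene clusters."""
    m = p.matrix.to_numpy()
    s = m.T @ m
    adj = np.sign(s)
    np.fill_diagonal(adj, 0)
    ids = list(p.matrix.columns)
    return (
        pd.DataFrame(s, index=ids, columns=ids),
        pd.DataFrame(adj, index=ids, columns=ids),
    )


def edge_weights(s: pd.DataFrame, l: pd.Series) -> pd.DataFrame:
    """Edge list with w = s/(l_a·l_b) for every genome pair sharing s > 0 clusters."""
    ids = list(s.index)
    arr = s.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            shared = int(arr[i, j])
            if shared == 0:
                continue
            la, lb = int(l[ids[i]]), int(l[ids[j]])
            rows.append((ids[i], ids[j], shared, shared / (la * lb), la, lb))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def filter_edges(
    edges: pd.DataFrame,
    minw: float = 0.0,
    mode: str = "minw",
    fraction: float = 0.30,
) -> pd.DataFrame:
    """Retain edges by the default strict rule w > minw, or by shared fraction.

    mode="fraction" keeps an edge iff s / min(l_a, l_b) >= fraction ("shares at
    least that fraction of the smaller genome's gene clusters").
    """
    if minw < 0:
        raise ValidationError("minw must be >= 0")
    if mode == "minw":
        kept = edges[edges["w"] > minw]
    elif mode == "fraction":
        frac = edges["s"] / np.minimum(edges["l_a"], edges["l_b"])
        kept = edges[frac >= fraction]
    else:
        raise ValidationError(f"unknown edge filter mode {mode!r}")
    return kept.reset_index(drop=True)


def connected_components(nodes: list, edges: pd.DataFrame) -> dict:
    """Union–find component labels, canonicalised by each component's smallest id.

    Labels are dense integers from 0, assigned in order of the (sorted)
    smallest member id, so the labelling is invariant to edge-list order.
    """
    nodes = list(nodes)
    node_set = set(nodes)
    parent = {v: v for v in nodes}

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:  # path compression
            parent[v], v = root, parent[v]
        return root

    for a, b in edges[["genome_a", "genome_b"]].itertuples(index=False):
        if a not in node_set or b not in node_set:
            raise DataError(f"edge endpoint not among nodes: ({a}, {b})")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), []).append(v)
    ordered = sorted(groups.values(), key=lambda ms: min(map(str, ms)))
    labels = {}
    for cid, members in enumerate(ordered):
        for v in members:
            labels[v] = cid
    return labels


@dataclass
class PhageNetwork:
    """Weighted prophage-sharing network after edge filtering."""

    nodes: list
    edges: pd.DataFrame  # EDGE_COLUMNS
    components: dict
    minw: float | None = None
    l: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return len(set(self.components.values()))


def build_network(
    p: PresenceMatrix,
    minw: float = 0.0,
    mode: str = "minw",
    fraction: float = 0.30,
) -> PhageNetwork:
    """Presence matrix -> filtered, component-labelled genome network."""
    s, _ = genome_adjacency(p)
    edges = filter_edges(edge_weights(s, p.l), minw=minw, mode=mode, fraction=fraction)
    comp = connected_components(p.genomes, edges)
    return PhageNetwork(p.genomes, edges, comp, minw=minw, l=p.l)


def export_network(net: PhageNetwork, outdir, taxonomy: dict | None = None) -> None:
    """Write edges.tsv, a SIF file for graph viewers, and a node attribute table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(net.edges[["genome_a", "genome_b", "s", "w"]], outdir / "edges.tsv")
    with open(outdir / "network.sif", "w", newline="\n") as fh:
        for a, b in net.edges[["genome_a", "genome_b"]].itertuples(index=False):
            fh.write(f"{a}\tsg\t{b}\n")
    nodes = pd.DataFrame(
        {
            "id": net.nodes,
            "component": [net.components[v] for v in net.nodes],
            "l": [int(net.l[v]) if net.l is not None else 0 for v in net.nodes],
            "taxonomy": [
                (taxonomy or {}).get(v, "Unknown") for v in net.nodes
            ],
        }
    )
    write_tsv(nodes, outdir / "nodes.tsv")


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
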