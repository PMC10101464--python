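"""Catalog summary statistics, percentage formatting, and pipeline orchestration.

Catalog reports quote ratios like "1,807 (59.48%)"; :func:`percent` reproduces
that style exactly, rounding half away from zero at the requested precision.
:func:`catalog_summary` tallies a whole catalog (completeness classes,
integrase/VF/ARG carriage, sequence-cluster statistics, gut-phageome tiers)
with conservation cross-checks, and :func:`run_pipeline` wires the simulated
cohort through every analysis stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import cluster as clustermod
from . import network as networkmod
from . import pangenome, screens
from .errors import IntegrityError, ValidationError
from .io import timed_stage, write_tsv
from .simulate import SimConfig, SimResult, simulate


def percent(numerator: int, denominator: int, decimals: int = 2) -> tuple[float, str]:
    """Fraction and printed percentage, rounded half away from zero.

    ``percent(1807, 3038, 2) -> (0.5948..., "59.48%")``; with ``decimals=0``
    the string carries no decimal point (``"95%"``).
    """
    if denominator <= 0:
        raise ValidationError("percent requires a positive denominator")
    fraction = numerator / denominator
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return fraction, f"{value}%"


@dataclass
class CatalogSummary:
    """Exact tallies of one catalog run, with printed-percentage companions."""

    n_genomes: int
    n_prophages: int
    completeness_counts: dict
    n_genomes_with_intact: int
    n_with_integrase: int
    n_with_vf: int
    n_with_arg: int
    n_clusters: int
    n_singletons: int
    largest_cluster: int
    gut_tier_counts: dict
    n_components: int | None = None
    percents: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["gut_tier_counts"] = {str(k): v for k, v in self.gut_tier_counts.items()}
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        flat = []
        for key, val in self.to_dict().items():
            if isinstance(val, dict):
                flat.extend((f"{key}.{k}", v) for k, v in val.items())
            else:
                flat.append((key, val))
        write_tsv(pd.DataFrame(flat, columns=["statistic", "value"]), path)


def catalog_summary(
    completeness: dict[str, str],
    prophage_genome: dict[str, str],
    integrase: dict[str, bool] | None = None,
    vf: dict[str, list] | None = None,
    arg: dict[str, list] | None = None,
    clusters: list | None = None,
    gut_tiers: dict | None = None,
    n_components: int | None = None,
) -> CatalogSummary:
    """Tally a catalog; refuses to report if cross-references are inconsistent.

    `completeness` maps every prophage to its class (intact/questionable/
    incomplete); `prophage_genome` maps each prophage to its source genome.
    The remaining stage outputs are optional and may cover a subset.
    """
    prophages = set(completeness)
    offenders = sorted(set(prophage_genome) ^ prophages)
    if offenders:
        raise IntegrityError(f"prophage/genome map mismatch: {offenders[:5]}")
    for name, mapping in (("integrase", integrase), ("vf", vf), ("arg", arg),
                          ("gut", gut_tiers)):
        unknown = sorted(set(mapping or {}) - prophages)
        if unknown:
            raise IntegrityError(f"{name} screen references unknown prophages: {unknown[:5]}")

    class_counts: dict[str, int] = {}
    for cls in completeness.values():
        class_counts[cls] = class_counts.get(cls, 0) + 1
    if sum(class_counts.values()) != len(prophages):
        raise IntegrityError("completeness class counts do not sum to total")

    genomes = set(prophage_genome.values())
    intact_genomes = {
        prophage_genome[p] for p, c in completeness.items() if c == "intact"
    }
    n_vf = sum(1 for genes in (vf or {}).values() if genes)
    n_arg = sum(1 for genes in (arg or {}).values() if genes)
    n_int = sum(1 for flag in (integrase or {}).values() if flag)

    if clusters:
        cs = clustermod.cluster_summary(clusters)
        n_clusters, n_singletons, largest = cs.n_clusters, cs.n_singletons, cs.largest_size
    else:
        n_clusters = n_singletons = largest = 0

    tier_counts: dict = {}
    for tier in (gut_tiers or {}).values():
        tier_counts[str(tier)] = tier_counts.get(str(tier), 0) + 1

    percents: dict[str, str] = {}
    if genomes:
        percents["genomes_with_intact"] = percent(
            len(intact_genomes), len(genomes), 0
        )[1]
    if prophages:
        percents["with_integrase"] = percent(n_int, len(prophages), 2)[1]
        percents["with_vf"] = percent(n_vf, len(prophages), 2)[1]
        percents["with_arg"] = percent(n_arg, len(prophages), 2)[1]
    if n_clusters:
        percents["singleton_clusters"] = percent(n_singletons, n_clusters, 2)[1]

    return CatalogSummary(
        n_genomes=len(genomes),
        n_prophages=len(prophages),
        completeness_counts=class_counts,
        n_genomes_with_intact=len(intact_genomes),
        n_with_integrase=n_int,
        n_with_vf=n_vf,
        n_with_arg=n_arg,
        n_clusters=n_clusters,
        n_singletons=n_singletons,
        largest_cluster=largest,
        gut_tier_counts=tier_counts,
        n_components=n_components,
        percents=percents,
    )


@dataclass
class PipelineResult:
    sim: SimResult
    gene_assignment: dict
    gene_edges: pd.DataFrame
    presence: networkmod.PresenceMatrix
    network: networkmod.PhageNetwork
    clusters: list
    summary: CatalogSummary


def run_pipeline(
    cfg: SimConfig,
    minw: float = 0.0,
    mcl_params: pangenome.MclParams | None = None,
    cluster_cfg: clustermod.ClusterConfig | None = None,
    minbit: float = 0.35,
    outdir=None,
) -> PipelineResult:
    """Simulate a cohort and run pangenome -> network -> clustering -> report."""
    mcl_params = mcl_params or pangenome.MclParams()
    cluster_cfg = cluster_cfg or clustermod.ClusterConfig()
    with timed_stage("simulate"):
        sim = simulate(cfg)
        if outdir is not None:
            sim.write(Path(outdir) / "sim")
    with timed_stage("pangenome"):
        assignment, edges = pangenome.cluster_genes(
            sim.genes, mcl_params, minbit=minbit
        )
        if outdir is not None:
            pangenome.write_outputs(assignment, edges, Path(outdir) / "pangenome")
    with timed_stage("network"):
        presence = networkmod.build_presence_matrix(assignment, sim.gene_to_genome())
        net = networkmod.build_network(presence, minw=minw)
        if outdir is not None:
            networkmod.export_network(net, Path(outdir) / "network")
    with timed_stage("cluster"):
        seq_clusters = clustermod.greedy_cluster(sim.genomes, cluster_cfg)
        if outdir is not None:
            clustermod.write_outputs(seq_clusters, sim.genomes, Path(outdir) / "cluster")
    with timed_stage("report"):
        integrase = screens.flag_integrase_all(sim.gene_table)
        summary = catalog_summary(
            completeness={g: "intact" for g in sim.genomes},
            prophage_genome={g: g for g in sim.genomes},
            integrase=integrase,
            clusters=seq_clusters,
            n_components=net.n_components,
        )
        if outdir is not None:
            rep = Path(outdir) / "report"
            rep.mkdir(parents=True, exist_ok=True)
            summary.to_json(rep / "summary.json")
            summary.to_tsv(rep / "summary.tsv")
    return PipelineResult(sim, assignment, edges, presence, net, seq_clusters, summary)
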