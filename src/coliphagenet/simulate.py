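"""Synthetic prophage cohorts with planted family structure.

Real prophage catalogs come from predicting integrated phages in thousands of
host genomes; that input cannot be bundled, so every downstream stage is
exercised on simulated cohorts with known ground truth instead. A cohort is
organised as ``n_families`` unrelated phage families. Each family owns
``modules_per_family`` gene modules (syntenic blocks of ``genes_per_module``
ancestral genes, drawn uniformly over {A,C,G,T}); module 0 is the core module
and is present in every genome of the family, while each accessory module is
carried independently with probability ``1 - mosaicism_rate``. Every gene copy
is the ancestral gene mutated i.i.d. per site at ``mutation_rate`` (a mutated
site always changes base, uniformly over the three alternatives), and a genome
is the concatenation of its gene copies in module order on the + strand.

Because family gene pools are disjoint, between-family sequence identity sits
at the random-DNA floor while within-family identity is controlled by
``mutation_rate`` — a planted signal that network construction, gene-family
clustering and species-level clustering should all recover.

The module also fabricates similarity hit tables with prescribed
coverage/identity, and spot-assay lysis matrices with prescribed host breadth,
so the screening and host-range stages are testable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import write_fasta, write_tsv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: product string attached to the first core-module gene of every genome, so
#: integrase flagging has a planted positive in every simulated prophage
INTEGRASE_PRODUCT = "site-specific integrase"
HYPOTHETICAL_PRODUCT = "hypothetical protein"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated prophage cohort.

    Defaults describe a small desk-scale cohort: three unrelated families of
    five genomes each, three modules of two 600 bp genes, 3% per-site
    divergence from the family ancestor and mild mosaicism.
    """

    n_families: int = 3
    modules_per_family: int = 3
    genes_per_module: int = 2
    genomes_per_family: int = 5
    mosaicism_rate: float = 0.1
    mutation_rate: float = 0.03
    gene_length: int = 600
    seed: int = 0

    def __post_init__(self):
        for name in ("n_families", "modules_per_family", "genes_per_module",
                     "genomes_per_family", "gene_length"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("mosaicism_rate", "mutation_rate"):
            p = float(getattr(self, name))
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass
class TruthTable:
    """Ground-truth labels for a simulated cohort.

    ``genomes`` maps genome_id -> family; ``genes`` maps each emitted gene copy
    to its (family, module, ancestor gene) of origin.
    """

    genomes: pd.DataFrame  # columns: genome_id, family
    genes: pd.DataFrame    # columns: gene_id, genome_id, family, module, ancestor

    def gene_labels(self, kind: str = "ancestor") -> dict[str, str]:
        """Per-gene truth labels: 'ancestor', 'module' (family×module) or 'family'."""
        g = self.genes
        if kind == "ancestor":
            lab = g["ancestor"]
        elif kind == "module":
            lab = g["family"].astype(str) + "|" + g["module"].astype(str)
        elif kind == "family":
            lab = g["family"].astype(str)
        else:
            raise ValueError(f"unknown label kind {kind!r}")
        return dict(zip(g["gene_id"], lab))

    def genome_families(self) -> dict[str, str]:
        return dict(zip(self.genomes["genome_id"], self.genomes["family"]))


@dataclass
class SimResult:
    """Everything one simulated cohort produces."""

    config: SimConfig
    genomes: dict[str, str]        # genome_id -> nucleotide sequence
    genes: dict[str, str]          # gene_id -> nucleotide sequence
    gene_table: pd.DataFrame       # gene_id, genome_id, start, end, strand, product
    truth: TruthTable

    def gene_to_genome(self) -> dict[str, str]:
        return dict(zip(self.gene_table["gene_id"], self.gene_table["genome_id"]))

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genomes.fasta", self.genomes)
        write_fasta(outdir / "genes.fasta", self.genes)
        write_tsv(self.gene_table, outdir / "genes.tsv")
        truth = self.truth.genes.merge(self.truth.genomes, on=["genome_id", "family"])
        write_tsv(truth, outdir / "truth.tsv")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site independently at `rate`; a hit always changes base."""
    out = codes.copy()
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size, dtype=np.uint8)
        out[hits] = (out[hits] + shift) % 4
    return out


def gen_gene_families(cfg: SimConfig) -> dict[str, str]:
    """Ancestral gene sequences, keyed ``F<f>M<m>G<g>``, from the seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    ancestors: dict[str, str] = {}
    for f in range(cfg.n_families):
        for m in range(cfg.modules_per_family):
            for g in range(cfg.genes_per_module):
                ancestors[f"F{f}M{m}G{g}"] = _to_str(_random_seq(rng, cfg.gene_length))
    return ancestors


def gen_prophage_genomes(cfg: SimConfig, ancestors: dict[str, str]) -> SimResult:
    """Emit genomes as mosaic, mutated copies of the family ancestors.

    Module 0 is the core module (always present); each accessory module is
    carried with probability ``1 - mosaicism_rate``. Coordinates in the gene
    table are 0-based half-open, strand always '+'.
    """
    # separate stream from gen_gene_families so regenerating ancestors alone
    # never perturbs genome draws
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    anc_codes = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for name, seq in ancestors.items()
    }
    for name in anc_codes:
        anc_codes[name] = np.searchsorted(_BASES, anc_codes[name])

    genomes: dict[str, str] = {}
    genes: dict[str, str] = {}
    rows = []
    truth_gene_rows = []
    truth_genome_rows = []
    for f in range(cfg.n_families):
        for s in range(cfg.genomes_per_family):
            genome_id = f"F{f}S{s}"
            truth_genome_rows.append((genome_id, f"F{f}"))
            parts: list[str] = []
            pos = 0
            for m in range(cfg.modules_per_family):
                if m > 0 and rng.random() < cfg.mosaicism_rate:
                    continue  # accessory module absent from this genome
                for g in range(cfg.genes_per_module):
                    anc = f"F{f}M{m}G{g}"
                    copy = _mutate(rng, anc_codes[anc], cfg.mutation_rate)
                    seq = _to_str(copy)
                    gene_id = f"{genome_id}|{anc}"
                    product = (
                        INTEGRASE_PRODUCT if m == 0 and g == 0 else HYPOTHETICAL_PRODUCT
                    )
                    genes[gene_id] = seq
                    rows.append(
                        (gene_id, genome_id, pos, pos + len(seq), "+", product)
                    )
                    truth_gene_rows.append((gene_id, genome_id, f"F{f}", f"M{m}", anc))
                    parts.append(seq)
                    pos += len(seq)
            genomes[genome_id] = "".join(parts)
    gene_table = pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "start", "end", "strand", "product"]
    )
    truth = TruthTable(
        genomes=pd.DataFrame(truth_genome_rows, columns=["genome_id", "family"]),
        genes=pd.DataFrame(
            truth_gene_rows,
            columns=["gene_id", "genome_id", "family", "module", "ancestor"],
        ),
    )
    return SimResult(cfg, genomes, genes, gene_table, truth)


def simulate(cfg: SimConfig) -> SimResult:
    """Convenience: ancestors + genomes in one call."""
    return gen_prophage_genomes(cfg, gen_gene_families(cfg))


# ---------------------------------------------------------------------------
# Hit tables and spot-assay matrices
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs", "scovs",
]


def gen_hit_table(spec: list[tuple], qlen: int = 1000) -> pd.DataFrame:
    """Fabricate similarity hits in the tabular search convention.

    Each spec row is ``(query, subject, qcov, pid)`` or
    ``(query, subject, qcov, pid, scov)``; percentages in [0, 100]. Subject
    coverage defaults to the query coverage. Alignment length, mismatches and
    bitscore are filled deterministically from the requested values; duplicate
    (query, subject) pairs are preserved as separate rows.
    """
    rows = []
    for entry in spec:
        if len(entry) == 4:
            query, subject, qcov, pid = entry
            scov = qcov
        elif len(entry) == 5:
            query, subject, qcov, pid, scov = entry
        else:
            raise ValidationError(f"hit spec must have 4 or 5 fields, got {entry!r}")
        for name, val in (("qcov", qcov), ("pid", pid), ("scov", scov)):
            if not 0.0 <= float(val) <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {val!r}")
        length = max(1, round(qlen * float(qcov) / 100.0))
        mismatch = round(length * (1.0 - float(pid) / 100.0))
        bitscore = round(2.0 * length * float(pid) / 100.0, 1)
        rows.append((query, subject, float(pid), length, mismatch, 0,
                     1, length, 1, length, 0.0, bitscore, float(qcov), float(scov)))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


@dataclass
class SpotAssayMatrix:
    """Long-format spot-assay lysis calls with replicate structure.

    ``lysis`` holds one boolean per (phage, strain, replicate): True means the
    spot completely cleared the lawn. ``strain_meta`` (optional) carries
    phylotype and source-group labels keyed by strain id.
    """

    lysis: pd.DataFrame  # columns: phage, strain, replicate, lysis (0/1)
    strain_meta: pd.DataFrame | None = None

    @property
    def phages(self) -> list[str]:
        return sorted(self.lysis["phage"].unique())

    @property
    def strains(self) -> list[str]:
        return sorted(self.lysis["strain"].unique())

    def write(self, path) -> None:
        df = self.lysis.copy()
        df["lysis"] = df["lysis"].astype(int)
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def read(cls, path, strains_path=None) -> "SpotAssayMatrix":
        df = pd.read_csv(path, dtype={"phage": str, "strain": str})
        df["lysis"] = df["lysis"].astype(bool)
        meta = pd.read_csv(strains_path, dtype=str) if strains_path else None
        return cls(df, meta)


def gen_spot_matrix(
    n_phages: int,
    n_strains: int,
    breadth: float,
    replicates: int = 4,
    seed: int = 0,
    noise: bool = False,
) -> SpotAssayMatrix:
    """Random lysis matrix: each phage lyses each strain with prob. `breadth`.

    Without noise the per-(phage, strain) call is drawn once and copied across
    replicates; with ``noise=True`` every replicate is an independent draw.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if not 0.0 <= breadth <= 1.0:
        raise ValidationError(f"breadth must be in [0, 1], got {breadth}")
    rng = np.random.default_rng(seed)
    phages = [f"phi{i}" for i in range(n_phages)]
    strains = [f"EC{j}" for j in range(n_strains)]
    rows = []
    for p in phages:
        for s in strains:
            if noise:
                calls = rng.random(replicates) < breadth
            else:
                calls = np.repeat(rng.random() < breadth, replicates)
            rows.extend((p, s, r, bool(c)) for r, c in enumerate(calls))
    return SpotAssayMatrix(
        pd.DataFrame(rows, columns=["phage", "strain", "replicate", "lysis"])
    )
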