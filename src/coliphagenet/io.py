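"""Shared readers/writers (FASTA, TSV/CSV) plus flat key=value run configuration.

FASTA handling goes through Biopython's SeqIO, so wrapped/unwrapped records and
CRLF line endings are tolerated transparently. All tabular files are
tab-separated UTF-8 with LF endings unless a format explicitly says CSV.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DataError

log = logging.getLogger("coliphagenet")

FASTA_WRAP = 70


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(levelname)s\t%(name)s\t%(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


@contextmanager
def timed_stage(stage: str):
    """Log entry/exit of a pipeline stage with elapsed wall time."""
    t0 = time.perf_counter()
    log.info("%s\tstart", stage)
    try:
        yield
    finally:
        log.info("%s\tdone in %.2fs", stage, time.perf_counter() - t0)


def read_fasta(path) -> dict[str, str]:
    """Read a nucleotide FASTA into an id -> uppercase sequence dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Flat key=value run configuration
# ---------------------------------------------------------------------------

#: keys accepted in a run-configuration file, with their coercions
CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "n_families": int,
    "modules_per_family": int,
    "genes_per_module": int,
    "genomes_per_family": int,
    "mosaicism_rate": float,
    "mutation_rate": float,
    "gene_length": int,
    "inflation": float,
    "minbit": float,
    "minw": float,
    "edge_mode": str,          # "minw" | "fraction"
    "fraction": float,
    "identity_threshold": float,
    "length_diff_cutoff": float,
    "word_length": int,
    "replicate_rule": str,     # "all" | "any"
    "log_level": str,
}


def parse_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """
    cfg: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
        try:
            cfg[key] = CONFIG_SCHEMA[key](value)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return cfg


def write_config_snapshot(cfg: dict, path) -> None:
    """Write the effective configuration next to the outputs, for provenance."""
    with open(path, "w", newline="\n") as fh:
        for key in sorted(cfg):
            fh.write(f"{key} = {cfg[key]}\n")
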