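"""Threshold screens over similarity hit tables and gene annotations.

Four classification screens applied to each prophage of the catalog:

* taxonomy — against a phage reference set: hits with query coverage
  strictly > 50% and identity strictly > 70% are high-confidence; the
  best such hit (by bitscore, then identity, then subject id) names the
  prophage, otherwise it is "Unknown";
* virulence factors — hits below 90% identity or covering less than 90% of
  the virulence-factor gene are discarded; survivors are reported as a
  deduplicated gene list per prophage;
* gut-phageome comparison — tiered: "match" at >= 50% query coverage and
  >= 70% identity, "full_coverage" at 100% query coverage and >= 96%
  identity, "identical" at 100% coverage and 100% identity (each tier a
  subset of the previous);
* integrase — flagged when any annotated gene product contains "integrase"
  (case-insensitive substring).

Antibiotic-resistance genes come from an external caller whose tabular
output is only tabulated here (per-prophage gene lists, descending
frequency table), never recomputed.

Hit tables follow the 12-column tabular search convention (qseqid sseqid
pident length mismatch gapopen qstart qend sstart send evalue bitscore),
optionally extended with query coverage (col 13, ``qcovs``) and subject
coverage (col 14, ``scovs``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import pandas as pd

from .errors import ParseError
from .simulate import HIT_COLUMNS


@dataclass(frozen=True)
class ScreenConfig:
    """All screen thresholds, in percent. Strictness follows each screen's rule."""

    tax_qcov: float = 50.0   # strict >
    tax_pid: float = 70.0    # strict >
    vf_pid: float = 90.0     # >=
    vf_subject_cov: float = 90.0  # >=
    gut_qcov: float = 50.0   # >=
    gut_pid: float = 70.0    # >=
    gut_full_qcov: float = 100.0
    gut_full_pid: float = 96.0
    identical_pid: float = 100.0


class GutTier(IntEnum):
    """Nested similarity tiers to the gut phageome (higher = stricter)."""

    NONE = 0
    MATCH = 1
    FULL_COVERAGE = 2
    IDENTICAL = 3

    def __str__(self) -> str:  # tier names as printed in reports
        return self.name.lower()


def read_hit_table(path, taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tabular hit file (12, 13 or 14 columns; no header).

    With 13 columns the last is query coverage; with 14 the last two are query
    and subject coverage. An optional subject -> taxonomy mapping adds a
    ``subject_taxonomy`` column.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13, 14):
                raise ParseError(
                    f"expected 12-14 tab-separated fields, got {len(fields)}", lineno
                )
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ParseError("inconsistent column count", lineno)
            try:
                rows.append(
                    fields[:2]
                    + [float(fields[2]), int(fields[3]), int(fields[4]),
                       int(fields[5]), int(fields[6]), int(fields[7]),
                       int(fields[8]), int(fields[9]), float(fields[10]),
                       float(fields[11])]
                    + [float(x) for x in fields[12:]]
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    df = pd.DataFrame(rows, columns=HIT_COLUMNS[:ncols or 12])
    if taxonomy is not None:
        df["subject_taxonomy"] = df["sseqid"].map(taxonomy)
    return df


def _tax_label(row: pd.Series) -> str:
    lab = row.get("subject_taxonomy")
    return str(lab) if isinstance(lab, str) and lab else str(row["sseqid"])


def assign_taxonomy(hits: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> str:
    """Best high-confidence hit names the prophage; no such hit -> "Unknown"."""
    if hits.empty:
        return "Unknown"
    ok = hits[(hits["qcovs"] > cfg.tax_qcov) & (hits["pident"] > cfg.tax_pid)]
    if ok.empty:
        return "Unknown"
    best = ok.sort_values(
        ["bitscore", "pident", "sseqid"], ascending=[False, False, True]
    ).iloc[0]
    return _tax_label(best)


def assign_taxonomy_all(
    hits: pd.DataFrame, prophages: list[str], cfg: ScreenConfig = ScreenConfig()
) -> dict[str, str]:
    by_query = dict(tuple(hits.groupby("qseqid"))) if len(hits) else {}
    return {
        p: assign_taxonomy(by_query.get(p, hits.iloc[0:0]), cfg) for p in prophages
    }


def vf_screen(
    hits: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()
) -> dict[str, list[str]]:
    """Virulence-factor genes surviving the identity/coverage filter, per prophage."""
    if hits.empty:
        return {}
    if "scovs" not in hits.columns:
        raise ParseError("virulence screen requires subject coverage (14-column hits)")
    kept = hits[(hits["pident"] >= cfg.vf_pid) & (hits["scovs"] >= cfg.vf_subject_cov)]
    return {
        q: sorted(sub["sseqid"].unique()) for q, sub in kept.groupby("qseqid")
    }


def gut_tier(hits: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> GutTier:
    """Strictest gut-phageome tier supported by any hit of one prophage."""
    if hits.empty:
        return GutTier.NONE
    q, p = hits["qcovs"], hits["pident"]
    if ((q >= cfg.gut_full_qcov) & (p >= cfg.identical_pid)).any():
        return GutTier.IDENTICAL
    if ((q >= cfg.gut_full_qcov) & (p >= cfg.gut_full_pid)).any():
        return GutTier.FULL_COVERAGE
    if ((q >= cfg.gut_qcov) & (p >= cfg.gut_pid)).any():
        return GutTier.MATCH
    return GutTier.NONE


def gut_compare(
    hits: pd.DataFrame, prophages: list[str], cfg: ScreenConfig = ScreenConfig()
) -> dict[str, GutTier]:
    by_query = dict(tuple(hits.groupby("qseqid"))) if len(hits) else {}
    return {p: gut_tier(by_query.get(p, hits.iloc[0:0]), cfg) for p in prophages}


def flag_integrase(products) -> bool:
    """True iff any product description contains "integrase" (case-insensitive)."""
    return any("integrase" in (p or "").lower() for p in products)


def flag_integrase_all(gene_table: pd.DataFrame) -> dict[str, bool]:
    """Per-genome integrase flag from a gene table with a ``product`` column."""
    out = {}
    for genome, sub in gene_table.groupby("genome_id"):
        out[str(genome)] = flag_integrase(sub["product"].fillna(""))
    return out


def arg_tabulate(
    table: pd.DataFrame,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Tabulate external resistance-caller rows (prophage_id, gene_name[, hit_class]).

    Returns per-prophage deduplicated gene lists and a gene frequency table
    sorted by descending prophage count (ties alphabetically). A gene is
    counted once per prophage carrying it.
    """
    if table.empty:
        return {}, pd.DataFrame(columns=["gene_name", "n_prophages"])
    dedup = table[["prophage_id", "gene_name"]].drop_duplicates()
    per = {
        str(p): sorted(sub["gene_name"]) for p, sub in dedup.groupby("prophage_id")
    }
    freq = (
        dedup.groupby("gene_name")
        .size()
        .reset_index(name="n_prophages")
        .sort_values(["n_prophages", "gene_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return per, freq
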