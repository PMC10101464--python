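"""Host-range and phage-cocktail arithmetic over spot-assay lysis matrices.

A spot assay drops phage lysate on a bacterial lawn; complete clearing scores
the strain as lysed. Technical replicates are first collapsed to one boolean
call per (phage, strain) — by default a strain counts as lysed only if every
replicate cleared ("all"; an "any" rule is also available). From the collapsed
matrix the module computes per-phage host counts over strain subsets, 2×2
pairwise susceptibility tables (both / A only / B only / neither), cocktail
coverage (strains lysed by at least one phage of a chosen set) and the best
size-k cocktail by exhaustive search.

Two worked-example fixtures ship with the package: the qualitative lysis
pattern of ten induced urinary coliphages plus urinary and laboratory phages
against 13 E. coli strains, and the 103-strain two-phage susceptibility counts
for the T2+N4 cocktail.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .simulate import SpotAssayMatrix


def aggregate_replicates(matrix: SpotAssayMatrix, rule: str = "all") -> pd.DataFrame:
    """Collapse replicates to a phage × strain boolean DataFrame.

    rule="all": lysed iff every replicate shows complete lysis (default);
    rule="any": lysed iff any replicate does. Identical for one replicate.
    """
    if rule not in ("all", "any"):
        raise ValidationError(f"unknown replicate rule {rule!r}")
    agg = matrix.lysis.groupby(["phage", "strain"])["lysis"].agg(rule)
    return agg.unstack("strain").fillna(False).astype(bool)


def _subset(agg: pd.DataFrame, strains) -> pd.DataFrame:
    if strains is None:
        return agg
    missing = [s for s in strains if s not in agg.columns]
    if missing:
        raise DataError(f"unknown strains: {missing}")
    return agg[list(strains)]


def host_count(agg: pd.DataFrame, phage: str, strains=None) -> int:
    """Number of strains (within the subset) completely lysed by `phage`."""
    if phage not in agg.index:
        raise DataError(f"unknown phage {phage!r}")
    return int(_subset(agg, strains).loc[phage].sum())


@dataclass
class PairTable:
    """2×2 susceptibility table for two phages over a strain panel."""

    phage_a: str
    phage_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def n_a(self) -> int:
        return self.n_both + self.n_a_only

    @property
    def n_b(self) -> int:
        return self.n_both + self.n_b_only

    @property
    def n_covered(self) -> int:
        """Strains lysed by at least one of the two phages."""
        return self.n_both + self.n_a_only + self.n_b_only


def pair_table(agg: pd.DataFrame, phage_a: str, phage_b: str, strains=None) -> PairTable:
    """Count both/A-only/B-only/neither lysis outcomes over a strain subset."""
    for p in (phage_a, phage_b):
        if p not in agg.index:
            raise DataError(f"unknown phage {p!r}")
    sub = _subset(agg, strains)
    a = sub.loc[phage_a].to_numpy()
    b = sub.loc[phage_b].to_numpy()
    return PairTable(
        phage_a,
        phage_b,
        n_both=int((a & b).sum()),
        n_a_only=int((a & ~b).sum()),
        n_b_only=int((~a & b).sum()),
        n_neither=int((~a & ~b).sum()),
    )


def cocktail_coverage(agg: pd.DataFrame, phages, strains=None) -> tuple[int, float]:
    """Strains lysed by >= 1 phage of the set: (count, fraction of the panel)."""
    phages = list(phages)
    if not phages:
        raise ValidationError("cocktail must contain at least one phage")
    for p in phages:
        if p not in agg.index:
            raise DataError(f"unknown phage {p!r}")
    sub = _subset(agg, strains)
    covered = sub.loc[phages].any(axis=0)
    n = int(covered.sum())
    return n, n / sub.shape[1]


def best_cocktail(agg: pd.DataFrame, k: int, strains=None) -> tuple[tuple, int]:
    """Exhaustively search all size-k phage sets; ties broken lexicographically."""
    phages = sorted(agg.index)
    if not 1 <= k <= len(phages):
        raise ValidationError(f"k must be in [1, {len(phages)}], got {k}")
    best: tuple | None = None
    best_n = -1
    for combo in combinations(phages, k):
        n, _ = cocktail_coverage(agg, combo, strains)
        if n > best_n:  # combinations() is lexicographic, so first max wins ties
            best, best_n = combo, n
    return best, best_n


def matrix_from_pair_counts(pt: PairTable) -> pd.DataFrame:
    """Expand a 2×2 pair table into an explicit two-phage boolean matrix.

    Strain ids are synthetic (``S000``...); the matrix reproduces the table's
    counts exactly and lets matrix-level operations run on count-only data.
    """
    patterns = (
        [(True, True)] * pt.n_both
        + [(True, False)] * pt.n_a_only
        + [(False, True)] * pt.n_b_only
        + [(False, False)] * pt.n_neither
    )
    data = np.array(patterns, dtype=bool).T
    strains = [f"S{i:03d}" for i in range(pt.n_total)]
    return pd.DataFrame(data, index=[pt.phage_a, pt.phage_b], columns=strains)


# ---------------------------------------------------------------------------
# Bundled worked-example fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("coliphagenet.data").joinpath(name)


def load_lysis_panel() -> SpotAssayMatrix:
    """Qualitative lysis panel: 19 phages × 13 E. coli strains, one replicate.

    Strains span three laboratory hosts (B, C, K-12) and ten urinary isolates;
    strain metadata carries phylotype and source group (UTI/OAB/laboratory).
    """
    with _data_path("table3.csv").open() as fh:
        wide = pd.read_csv(fh, dtype={"phage": str}).set_index("phage")
    wide.columns = wide.columns.astype(str)
    long = (
        wide.astype(bool)
        .stack()
        .reset_index()
        .rename(columns={"level_1": "strain", 0: "lysis"})
    )
    long["replicate"] = 0
    with _data_path("strains.csv").open() as fh:
        meta = pd.read_csv(fh, dtype=str)
    return SpotAssayMatrix(
        long[["phage", "strain", "replicate", "lysis"]], strain_meta=meta
    )


def urinary_strains(matrix: SpotAssayMatrix) -> list[str]:
    """Strain ids of urinary (non-laboratory) isolates, in panel order."""
    meta = matrix.strain_meta
    if meta is None:
        raise DataError("panel has no strain metadata")
    return list(meta.loc[meta["group"] != "laboratory", "strain"])


def load_pair_counts() -> PairTable:
    """Two-phage susceptibility counts for T2 and N4 over 103 urinary strains."""
    with _data_path("table4_counts.csv").open() as fh:
        counts = pd.read_csv(fh).set_index("category")["count"]
    return PairTable(
        "T2",
        "N4",
        n_both=int(counts["both"]),
        n_a_only=int(counts["t2_only"]),
        n_b_only=int(counts["n4_only"]),
        n_neither=int(counts["neither"]),
    )
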