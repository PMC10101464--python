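"""Species-level greedy incremental clustering of prophage sequences.

Whole prophage sequences are grouped at approximately the species rank with
the classic greedy incremental scheme: sort sequences longest-first, scan in
order, and let each sequence join the first existing cluster whose
representative it matches; otherwise it founds a new cluster and becomes that
cluster's representative. A candidate matches a representative when all of

* length: shorter/longer >= ``length_diff_cutoff`` (default 0.8),
* word prescreen: the pair shares at least one word of ``word_length``
  (default 4) nucleotides,
* identity: pairwise identity >= ``identity_threshold`` (default 0.8)

hold. Identity is defined against the shorter sequence: the shorter sequence
is aligned within the longer (semi-global, free end gaps on the longer) and

    identity = 1 − edit_distance / len(shorter)

floored at 0. Representatives are therefore always the longest member of
their cluster, and any two representatives fail at least one criterion.
Output mirrors the familiar ``.clstr`` text format, with the representative
line ending in ``*``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from .errors import DataError, ValidationError
from .io import write_fasta, write_tsv


@dataclass(frozen=True)
class ClusterConfig:
    identity_threshold: float = 0.80
    length_diff_cutoff: float = 0.80
    word_length: int = 4
    #: advisory band half-width for banded-DP backends; the edit-distance
    #: backend used here manages its own banding internally
    band_width: int | None = None

    def __post_init__(self):
        for name in ("identity_threshold", "length_diff_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.word_length < 2:
            raise ValidationError("word_length must be >= 2")


@dataclass
class SequenceCluster:
    cluster_id: int
    representative_id: str
    members: list  # (seq_id, identity_to_rep, length); representative first

    @property
    def size(self) -> int:
        return len(self.members)


def pairwise_identity(seq_a: str, seq_b: str, cfg: ClusterConfig = ClusterConfig()) -> float:
    """Identity of the shorter sequence aligned within the longer, in [0, 1].

    On equal lengths the first argument plays the query role (semi-global
    alignment is direction-dependent, though rarely by more than one edit).
    """
    if not seq_a or not seq_b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    shorter, longer = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    d = edlib.align(shorter, longer, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(shorter))


def _shares_word(seq_a: str, seq_b: str, k: int) -> bool:
    if len(seq_a) < k or len(seq_b) < k:
        return False
    words = {seq_a[i:i + k] for i in range(len(seq_a) - k + 1)}
    return any(seq_b[i:i + k] in words for i in range(len(seq_b) - k + 1))


def greedy_cluster(
    sequences, cfg: ClusterConfig = ClusterConfig()
) -> list[SequenceCluster]:
    """Greedy incremental clustering; first-fit join in longest-first scan order.

    ``sequences`` is an id -> sequence mapping or an iterable of (id, sequence)
    pairs; duplicate ids are rejected.
    """
    if not isinstance(sequences, dict):
        pairs = list(sequences)
        sequences = dict(pairs)
        if len(sequences) != len(pairs):
            raise DataError("duplicate sequence ids")
    if not sequences:
        raise ValidationError("greedy_cluster requires at least one sequence")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters: list[SequenceCluster] = []
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cl in clusters:
            rep_seq = sequences[cl.representative_id]
            if len(seq) / len(rep_seq) < cfg.length_diff_cutoff:
                continue
            if not _shares_word(rep_seq, seq, cfg.word_length):
                continue
            ident = pairwise_identity(seq, rep_seq, cfg)
            if ident >= cfg.identity_threshold:
                cl.members.append((sid, ident, len(seq)))
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(len(clusters), sid, [(sid, 1.0, len(seq))])
            )
    return clusters


# ---------------------------------------------------------------------------
# .clstr-style serialisation
# ---------------------------------------------------------------------------


def write_clstr(clusters: list[SequenceCluster], path=None) -> str:
    """Render clusters in .clstr text form; representative lines end with '*'."""
    lines = []
    for cl in clusters:
        lines.append(f">Cluster {cl.cluster_id}")
        for i, (sid, ident, length) in enumerate(cl.members):
            if sid == cl.representative_id:
                lines.append(f"{i}\t{length}nt, >{sid}... *")
            else:
                lines.append(f"{i}\t{length}nt, >{sid}... at +/{ident * 100:.2f}%")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, newline="\n")
    return text


_MEMBER_RE = re.compile(
    r"^\d+\t(?P<len>\d+)nt, >(?P<id>.+?)\.\.\. (?:\*|at \+/(?P<pct>[\d.]+)%)$"
)


def parse_clstr(text: str) -> list[SequenceCluster]:
    """Parse .clstr text written by :func:`write_clstr` back into clusters."""
    clusters: list[SequenceCluster] = []
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith(">Cluster"):
            clusters.append(SequenceCluster(int(line.split()[1]), "", []))
            continue
        m = _MEMBER_RE.match(line)
        if m is None or not clusters:
            raise DataError(f"unparseable .clstr line: {line!r}")
        sid, length = m.group("id"), int(m.group("len"))
        if m.group("pct") is None:
            clusters[-1].representative_id = sid
            clusters[-1].members.append((sid, 1.0, length))
        else:
            clusters[-1].members.append((sid, float(m.group("pct")) / 100.0, length))
    return clusters


@dataclass
class ClusterSummary:
    n_clusters: int
    n_singletons: int
    singleton_fraction: float
    largest_size: int
    rep_lengths: pd.DataFrame  # cluster_id, representative_id, rep_length, size


def cluster_summary(clusters: list[SequenceCluster]) -> ClusterSummary:
    """Counts used in catalog reporting (cluster sizes vs representative lengths)."""
    if not clusters:
        raise ValidationError("cluster_summary requires at least one cluster")
    sizes = [cl.size for cl in clusters]
    n_single = sum(1 for s in sizes if s == 1)
    rep_lengths = pd.DataFrame(
        {
            "cluster_id": [cl.cluster_id for cl in clusters],
            "representative_id": [cl.representative_id for cl in clusters],
            "rep_length": [
                next(l for sid, _, l in cl.members if sid == cl.representative_id)
                for cl in clusters
            ],
            "size": sizes,
        }
    )
    return ClusterSummary(
        n_clusters=len(clusters),
        n_singletons=n_single,
        singleton_fraction=n_single / len(clusters),
        largest_size=max(sizes),
        rep_lengths=rep_lengths,
    )


def write_outputs(
    clusters: list[SequenceCluster], sequences: dict[str, str], outdir
) -> None:
    """Write clusters.clstr, clusters.tsv and representatives.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_clstr(clusters, outdir / "clusters.clstr")
    rows = [
        (cl.cluster_id, sid, cl.representative_id, round(ident, 6), length)
        for cl in clusters
        for sid, ident, length in cl.members
    ]
    write_tsv(
        pd.DataFrame(
            rows,
            columns=["cluster_id", "seq_id", "representative_id", "identity", "length"],
        ),
        outdir / "clusters.tsv",
    )
    write_fasta(
        outdir / "representatives.fasta",
        {cl.representative_id: sequences[cl.representative_id] for cl in clusters},
    )
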