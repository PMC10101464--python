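import numpy as np
import pytest

from coliphagenet.cluster import (
    ClusterConfig,
    cluster_summary,
    greedy_cluster,
    pairwise_identity,
    parse_clstr,
    write_clstr,
)
from coliphagenet.errors import DataError, ValidationError
from oracles import infix_edit_distance


def random_dna(rng, n):
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_substituted_copy_matches_full_dp_oracle(self, rng):
        base = random_dna(rng, 1000)
        positions = rng.choice(1000, size=100, replace=False)
        mutant = list(base)
        for i in positions:
            mutant[i] = rng.choice([b for b in "ACGT" if b != mutant[i]])
        mutant = "".join(mutant)
        # equal lengths: the first argument plays the query role
        d = infix_edit_distance(base, mutant)
        assert pairwise_identity(base, mutant) == pytest.approx(1 - d / 1000)
        # shifted micro-repeats can repair the odd substitution via indel pairs,
        # so the distance sits at (or just under) the 100 planted substitutions
        assert 0.89 <= pairwise_identity(base, mutant) <= 0.92

    def test_indel_copy_matches_full_dp_oracle(self, rng):
        base = random_dna(rng, 400)
        # delete a block and insert another elsewhere
        mutant = base[:100] + base[130:300] + random_dna(rng, 15) + base[300:]
        shorter = min(base, mutant, key=len)
        d = infix_edit_distance(
            shorter, max(base, mutant, key=len)
        )
        assert pairwise_identity(base, mutant) == pytest.approx(
            max(0.0, 1 - d / len(shorter))
        )

    def test_shorter_within_longer(self):
        # the shorter sequence embedded exactly in the longer scores 1.0
        inner = "ACGTTGCAACGT"
        assert pairwise_identity(inner, "GGGG" + inner + "CCCC") == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "ACGT")


def oracle_greedy(sequences, cfg):
    """Independent re-application of the join rule with the DP-oracle identity."""
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters = []  # list of (rep_id, [members])
    for sid in order:
        seq = sequences[sid]
        for rep, members in clusters:
            rep_seq = sequences[rep]
            if len(seq) / len(rep_seq) < cfg.length_diff_cutoff:
                continue
            words = {
                rep_seq[i:i + cfg.word_length]
                for i in range(len(rep_seq) - cfg.word_length + 1)
            }
            if not any(
                seq[i:i + cfg.word_length] in words
                for i in range(len(seq) - cfg.word_length + 1)
            ):
                continue
            d = infix_edit_distance(seq, rep_seq)
            if 1 - d / len(seq) >= cfg.identity_threshold:
                members.append(sid)
                break
        else:
            clusters.append((sid, [sid]))
    return [frozenset(m) for _, m in clusters]


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = {"s1": "ACGT" * 10, "s2": "ACGT" * 10, "s3": "ACGT" * 10}
        clusters = greedy_cluster(seqs)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "s1"  # ties by id ascending
        assert clusters[0].size == 3

    def test_length_ratio_forces_split(self, rng):
        long = random_dna(rng, 1000)
        short = long[:700]  # identical content, ratio 0.7 < 0.8
        clusters = greedy_cluster({"long": long, "short": short})
        assert len(clusters) == 2

    def test_identity_boundary(self, rng):
        base = random_dna(rng, 1000)
        at_threshold = mutate(rng, base, 0.0)
        # exactly 200 substitutions -> identity 0.80, >= threshold: joins
        pos = rng.choice(1000, size=200, replace=False)
        lst = list(base)
        for i in pos:
            lst[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[lst[i]]
        at_threshold = "".join(lst)
        clusters = greedy_cluster({"a_base": base, "b_mut": at_threshold})
        assert len(clusters) == 1

    def test_planted_cluster_plus_singletons_matches_oracle(self, rng):
        ancestor = random_dna(rng, 800)
        seqs = {f"kin{i}": mutate(rng, ancestor, 0.05) for i in range(10)}
        seqs.update({f"rand{i}": random_dna(rng, 800) for i in range(5)})
        cfg = ClusterConfig()
        clusters = greedy_cluster(seqs, cfg)
        got = {frozenset(sid for sid, _, _ in cl.members) for cl in clusters}
        assert got == set(oracle_greedy(seqs, cfg))
        sizes = sorted(cl.size for cl in clusters)
        assert sizes == [1, 1, 1, 1, 1, 10]

    def test_matches_oracle_on_mixed_pool(self, rng):
        # several families, varying lengths, <= 50 sequences
        seqs = {}
        for f in range(4):
            anc = random_dna(rng, int(rng.integers(300, 700)))
            for i in range(int(rng.integers(3, 8))):
                s = mutate(rng, anc, 0.06)
                if rng.random() < 0.3:  # truncate some members
                    s = s[: int(len(s) * rng.uniform(0.75, 1.0))]
                seqs[f"f{f}m{i}"] = s
        for i in range(8):
            seqs[f"r{i}"] = random_dna(rng, int(rng.integers(300, 700)))
        cfg = ClusterConfig()
        got = {
            frozenset(sid for sid, _, _ in cl.members)
            for cl in greedy_cluster(seqs, cfg)
        }
        assert got == set(oracle_greedy(seqs, cfg))

    def test_representative_is_longest_member(self, rng):
        anc = random_dna(rng, 600)
        seqs = {
            "short1": mutate(rng, anc, 0.03)[:500],
            "full": mutate(rng, anc, 0.03),
            "short2": mutate(rng, anc, 0.03)[:520],
        }
        for cl in greedy_cluster(seqs):
            rep_len = len(seqs[cl.representative_id])
            assert all(rep_len >= length for _, _, length in cl.members)

    def test_order_invariance(self, rng):
        anc = random_dna(rng, 500)
        seqs = {f"s{i}": mutate(rng, anc, 0.04) for i in range(6)}
        seqs["odd"] = random_dna(rng, 500)
        base = [
            (cl.representative_id, frozenset(s for s, _, _ in cl.members))
            for cl in greedy_cluster(seqs)
        ]
        shuffled = dict(
            (k, seqs[k]) for k in [list(seqs)[i] for i in rng.permutation(len(seqs))]
        )
        assert base == [
            (cl.representative_id, frozenset(s for s, _, _ in cl.members))
            for cl in greedy_cluster(shuffled)
        ]

    def test_partition_property(self, rng):
        seqs = {f"s{i}": random_dna(rng, 300) for i in range(12)}
        clusters = greedy_cluster(seqs)
        seen = [sid for cl in clusters for sid, _, _ in cl.members]
        assert sorted(seen) == sorted(seqs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            greedy_cluster({})


class TestClstrFormat:
    def test_single_member_cluster(self):
        clusters = greedy_cluster({"only": "ACGTACGTAC"})
        text = write_clstr(clusters)
        lines = text.strip().splitlines()
        assert lines[0] == ">Cluster 0"
        assert lines[1].endswith("*")
        assert len(lines) == 2

    def test_percent_has_two_decimals(self, rng):
        anc = random_dna(rng, 500)
        seqs = {"a_rep": anc, "b_kin": mutate(rng, anc, 0.1)}
        text = write_clstr(greedy_cluster(seqs))
        member_line = [l for l in text.splitlines() if "at +/" in l][0]
        pct = member_line.split("at +/")[1]
        assert pct.endswith("%")
        whole, frac = pct[:-1].split(".")
        assert len(frac) == 2

    def test_round_trip(self, rng):
        anc = random_dna(rng, 400)
        seqs = {f"s{i}": mutate(rng, anc, 0.05) for i in range(4)}
        seqs["lone"] = random_dna(rng, 380)
        clusters = greedy_cluster(seqs)
        back = parse_clstr(write_clstr(clusters))
        assert [cl.representative_id for cl in back] == [
            cl.representative_id for cl in clusters
        ]
        assert [
            {s for s, _, _ in cl.members} for cl in back
        ] == [{s for s, _, _ in cl.members} for cl in clusters]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError):
            greedy_cluster([("a", "ACGT"), ("a", "ACGG")])


class TestSummary:
    def test_counts(self, rng):
        anc = random_dna(rng, 500)
        seqs = {f"kin{i}": mutate(rng, anc, 0.03) for i in range(3)}
        seqs["x_lone"] = random_dna(rng, 480)
        seqs["y_lone"] = random_dna(rng, 470)
        cs = cluster_summary(greedy_cluster(seqs))
        assert cs.n_clusters == 3
        assert cs.n_singletons == 2
        assert cs.singleton_fraction == pytest.approx(2 / 3)
        assert cs.largest_size == 3
        assert set(cs.rep_lengths["size"]) == {1, 3}

    def test_all_singletons(self, rng):
        seqs = {f"s{i}": random_dna(rng, 300) for i in range(4)}
        cs = cluster_summary(greedy_cluster(seqs))
        assert cs.singleton_fraction == 1.0

    def test_singleton_fraction_printed_style(self):
        from coliphagenet.report import percent

        assert percent(1115, 1542, 2)[1] == "72.31%"
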