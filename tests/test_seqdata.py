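"""Dataset construction: FASTA IO, filters, identity clustering, splits,
negative screening and artificial decoys."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famprobe.seqdata import (CANONICAL, SequenceCluster, SequenceRecord,
                              filter_records, generate_artificial_negatives,
                              greedy_identity_cluster, pairwise_identity,
                              read_fasta, screen_negatives, split_by_cluster,
                              write_fasta)

AA = st.sampled_from(CANONICAL)
SEQ = st.text(alphabet=CANONICAL, min_size=1, max_size=60)


def rec(i, seq, source="positive"):
    return SequenceRecord(id=str(i), seq=seq, source=source)


# ------------------------------------------------------------------ FASTA IO
class TestFastaIO:
    def test_single_record_read_back(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMKV\n")
        out = read_fasta(p)
        assert [(r.id, r.seq) for r in out] == [("a", "MKV")]

    def test_duplicate_headers_get_numeric_suffix(self, tmp_path):
        p = tmp_path / "d.fasta"
        p.write_text(">x desc\nMKV\n>x other\nMLW\n")
        out = read_fasta(p)
        assert [r.id for r in out] == ["x", "x_2"]

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(p) == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seqs=st.lists(SEQ, min_size=1, max_size=5))
    def test_write_read_round_trip(self, seqs):
        import tempfile
        records = [rec(i, s) for i, s in enumerate(seqs)]
        with tempfile.TemporaryDirectory() as tmp:
            path = f"{tmp}/x.fasta"
            write_fasta(records, path)
            back = read_fasta(path)
        assert [r.seq for r in back] == seqs


# ----------------------------------------------------------------- filtering
class TestFiltering:
    def test_length_window_is_closed_interval(self):
        records = [rec(n, "A" * n) for n in (399, 400, 700, 701)]
        kept, prov = filter_records(records)
        assert sorted(len(r.seq) for r in kept) == [400, 700]
        verdicts = {rid: rule for rid, rule, _ in prov}
        assert verdicts["399"] == "length" and verdicts["701"] == "length"

    def test_non_canonical_letter_dropped(self):
        seq = "A" * 399 + "B"
        kept, prov = filter_records([rec("x", seq)])
        assert kept == [] and prov == [("x", "non_canonical", "dropped")]

    def test_exact_duplicate_keeps_first(self):
        a, b = rec("a", "A" * 500), rec("b", "A" * 500)
        kept, prov = filter_records([a, b])
        assert [r.id for r in kept] == ["a"]
        assert ("b", "duplicate", "dropped") in prov

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(3)
        records = [rec(i, "".join(rng.choice(list(CANONICAL + "X"),
                                             size=rng.integers(300, 800))))
                   for i in range(30)]
        once, _ = filter_records(records)
        twice, prov2 = filter_records(once)
        assert once == twice
        assert all(v == "kept" for _, _, v in prov2)

    def test_one_verdict_per_input_record(self):
        records = [rec(i, "A" * (390 + i)) for i in range(20)]
        _, prov = filter_records(records)
        assert sorted(rid for rid, _, _ in prov) == sorted(r.id for r in records)


# --------------------------------------------------------- pairwise identity
def lcs_identity_oracle(a: str, b: str) -> float:
    """Independent DP: maximum aligned identical positions / shorter length."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(dp[i - 1, j - 1] + (a[i - 1] == b[j - 1]),
                           dp[i - 1, j], dp[i, j - 1])
    return dp[n, m] / min(n, m)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVLW", "MKVLW") == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetry_and_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = "".join(rng.choice(list(CANONICAL), size=50))
            b = "".join(rng.choice(list(CANONICAL), size=50))
            ours = pairwise_identity(a, b)
            assert ours == pytest.approx(lcs_identity_oracle(a, b))
            assert ours == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


# ----------------------------------------------------------------- clustering
def greedy_oracle(records, threshold):
    """Brute-force re-statement of the greedy rule with the oracle identity."""
    order = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters = []
    for r in order:
        for cl in clusters:
            if lcs_identity_oracle(r.seq, cl[0].seq) >= threshold:
                cl.append(r)
                break
        else:
            clusters.append([r])
    return [[m.id for m in cl] for cl in clusters]


class TestGreedyCluster:
    def test_copies_form_single_cluster(self):
        records = [rec(i, "MKVLWAYN" * 10) for i in range(5)]
        clusters = greedy_identity_cluster(records, 0.95)
        assert len(clusters) == 1 and len(clusters[0].members) == 5

    def test_dissimilar_records_stay_singletons(self):
        rng = np.random.default_rng(4)
        records = [rec(i, "".join(rng.choice(list(CANONICAL), size=80)))
                   for i in range(8)]
        clusters = greedy_identity_cluster(records, 0.99)
        assert all(len(c.members) == 1 for c in clusters)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        bases = ["".join(rng.choice(list(CANONICAL), size=60)) for _ in range(4)]
        records = []
        for i in range(30):
            base = list(bases[i % 4])
            for _ in range(rng.integers(0, 4)):   # light mutation
                base[rng.integers(len(base))] = CANONICAL[rng.integers(20)]
            records.append(rec(i, "".join(base)))
        ours = [c.members for c in greedy_identity_cluster(records, 0.9)]
        assert ours == greedy_oracle(records, 0.9)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            greedy_identity_cluster([rec(0, "MKV")], 1.5)

    def test_invariant_to_duplicating_the_seed(self):
        records = [rec(i, "MKVLWAYNEH" * 8) for i in range(3)]
        one = greedy_identity_cluster(records, 0.9)
        dup = greedy_identity_cluster(records + [rec(9, "MKVLWAYNEH" * 8)], 0.9)
        assert len(one) == len(dup) == 1


# -------------------------------------------------------------------- splits
def make_clusters(sizes):
    out, n = [], 0
    for cid, size in enumerate(sizes):
        out.append(SequenceCluster(cid, [f"r{n + i}" for i in range(size)], 0.95))
        n += size
    return out


class TestSplitByCluster:
    def test_cluster_of_five_contributes_one_per_partition(self):
        clusters = make_clusters([5])
        split = split_by_cluster(clusters, seed=1)
        assert len(split.mapping) == 3
        assert sorted(split.mapping.values()) == ["test", "train", "validation"]
        assert set(split.mapping) <= set(clusters[0].members)

    def test_size_two_cluster_train_plus_one(self):
        for seed in range(10):
            split = split_by_cluster(make_clusters([2]), seed=seed)
            parts = sorted(split.mapping.values())
            assert "train" in parts
            assert parts.count("train") == 1
            assert parts[0] in ("test", "validation") or parts[1] in ("test", "validation")

    def test_size_two_members_never_colocated(self):
        for seed in range(25):
            split = split_by_cluster(make_clusters([2, 2, 2]), seed=seed)
            for cl in make_clusters([2, 2, 2]):
                a, b = cl.members
                assert split.mapping[a] != split.mapping[b]

    def test_hundred_singletons_near_8_1_1_and_reproducible(self):
        clusters = make_clusters([1] * 100)
        split = split_by_cluster(clusters, seed=42)
        counts = {p: list(split.mapping.values()).count(p)
                  for p in ("train", "validation", "test")}
        assert abs(counts["train"] - 80) <= 2
        assert abs(counts["validation"] - 10) <= 2
        assert abs(counts["test"] - 10) <= 2
        again = split_by_cluster(clusters, seed=42)
        assert again.mapping == split.mapping

    def test_surplus_to_train_flag(self):
        split = split_by_cluster(make_clusters([6]), seed=0, surplus_to_train=True)
        assert len(split.mapping) == 6
        assert sorted(split.mapping.values()).count("train") == 4

    def test_empty_cluster_list(self):
        assert split_by_cluster([], seed=0).mapping == {}


# ---------------------------------------------------------- negative screening
class TestScreenNegatives:
    def test_verbatim_copy_is_dropped(self):
        pos = [rec("p", "MKVLWAYNEH" * 45)]
        neg = [rec("n", "MKVLWAYNEH" * 45, "negative")]
        kept, dropped = screen_negatives(neg, pos)
        assert kept == [] and [d.id for d in dropped] == ["n"]

    def test_unrelated_negative_is_kept(self):
        pos = [rec("p", "ACDEFGHIKL" * 45)]
        neg = [rec("n", "MNPQRSTVWY" * 45, "negative")]
        kept, _ = screen_negatives(neg, pos)
        assert [k.id for k in kept] == ["n"]

    def test_random_sequences_rarely_collide(self):
        # chance 15-mer collisions between unrelated random proteins are
        # essentially impossible; over 200 trials at least 99% survive
        rng = np.random.default_rng(23)
        pos = [rec(f"p{i}", "".join(rng.choice(list(CANONICAL), size=500)))
               for i in range(5)]
        neg = [rec(f"n{i}", "".join(rng.choice(list(CANONICAL), size=500)),
                   "negative") for i in range(200)]
        kept, _ = screen_negatives(neg, pos)
        assert len(kept) >= 198

    def test_external_mode_needs_hit_table(self):
        with pytest.raises(ValueError):
            screen_negatives([], [], mode="external")

    def test_external_mode_drops_by_evalue(self, tmp_path):
        hits = tmp_path / "hits.tsv"
        hits.write_text("q1\tn1\t1e-30\nq1\tn2\t0.5\n")
        neg = [rec("n1", "A" * 400, "negative"), rec("n2", "C" * 400, "negative")]
        kept, dropped = screen_negatives(neg, [], mode="external", hit_table=hits)
        assert [k.id for k in kept] == ["n2"]
        assert [d.id for d in dropped] == ["n1"]


# ---------------------------------------------------------- artificial decoys
class TestArtificialNegatives:
    def test_default_yields_400_distinct_repeat_sequences(self):
        out = generate_artificial_negatives(seed=0)
        assert len(out) == 400
        assert len({r.seq for r in out}) == 400
        assert all(r.source == "artificial" for r in out)

    def test_lengths_and_period(self):
        out = generate_artificial_negatives(seed=1)
        for r in out:
            assert 400 <= len(r.seq) <= 700
            # period <= 2: every position equals the one two before it
            assert all(r.seq[i] == r.seq[i % 2] for i in range(len(r.seq)))

    def test_odd_truncation_ends_on_first_letter(self):
        out = generate_artificial_negatives(min_len=5, max_len=5, seed=0)
        ac = next(r for r in out if r.id == "art_AC")
        assert ac.seq == "ACACA"

    def test_seed_determinism_and_validation(self):
        assert generate_artificial_negatives(seed=7) == \
            generate_artificial_negatives(seed=7)
        with pytest.raises(ValueError):
            generate_artificial_negatives(min_len=10, max_len=5)
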