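from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_force_greedy_clusters, lcs_dp
from rdrpscout import cluster as clu
from rdrpscout.seqio import SeedAlignment

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seqs(rng, n, lo=5, hi=30):
    return [
        (f"s{i}", "".join(rng.choice(list(AA), size=rng.integers(lo, hi))))
        for i in range(n)
    ]


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACD", "ACD", 1.0),
            ("ACD", "ACDE", 1.0),  # exact prefix: shorter-length denominator
            ("AAAA", "CCCC", 0.0),
            ("ACDF", "AXDF", 3 / 4),  # X never counts as an identity
        ],
    )
    def test_known_pairs(self, a, b, expected):
        assert clu.pairwise_identity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            clu.pairwise_identity("", "ACD")

    def test_matches_textbook_lcs(self, rng):
        for _ in range(30):
            (_, a), (_, b) = _rand_seqs(rng, 2, 3, 25)
            assert clu.lcs_identity_count(a, b) == lcs_dp(a, b)


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        seqs = [("a", "MKVLD"), ("b", "MKVLD"), ("c", "MKVLD")]
        clusters = clu.greedy_cluster(seqs, 0.9)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b", "c"]

    def test_threshold_separates_at_60_percent_identity(self):
        a = "MKVLDWERTG"  # identity 6/10 with b
        b = "MKVLDWAAAA"
        assert clu.pairwise_identity(a, b) == pytest.approx(0.6)
        assert len(clu.greedy_cluster([("a", a), ("b", b)], 0.70)) == 2
        assert len(clu.greedy_cluster([("a", a), ("b", b)], 0.50)) == 1

    def test_matches_brute_force_oracle(self, rng):
        """200 random <= 12-sequence inputs against the ordered-rule oracle."""
        for trial in range(200):
            seqs = _rand_seqs(rng, int(rng.integers(2, 13)), 4, 20)
            for thr in (0.5, 0.7, 0.9, 1.0):
                ours = [
                    (c.representative, sorted(c.members))
                    for c in clu.greedy_cluster(seqs, thr)
                ]
                oracle = [
                    (rep, sorted(members))
                    for rep, members in brute_force_greedy_clusters(
                        seqs, thr, clu.pairwise_identity
                    )
                ]
                assert ours == oracle, (trial, thr)

    def test_cluster_count_monotone_in_threshold(self, rng):
        for _ in range(20):
            seqs = _rand_seqs(rng, 10, 4, 20)
            counts = [len(clu.greedy_cluster(seqs, t)) for t in (0.5, 0.7, 0.9, 1.0)]
            assert counts == sorted(counts)

    def test_threshold_one_on_unique_sequences_gives_singletons(self, rng):
        seqs = list({s: None for _, s in _rand_seqs(rng, 12, 6, 20)})
        seqs = [(f"u{i}", s) for i, s in enumerate(seqs)]
        # drop sequences contained in others (identity 1.0 by the shorter)
        kept = [
            (i, s)
            for i, s in seqs
            if not any(
                s != t and clu.pairwise_identity(s, t) == 1.0 for _, t in seqs
            )
        ]
        clusters = clu.greedy_cluster(kept, 1.0)
        assert len(clusters) == len(kept)

    def test_members_meet_threshold_to_representative(self, rng):
        seqs = _rand_seqs(rng, 15, 4, 20)
        by_id = dict(seqs)
        for thr in (0.5, 0.7):
            for cl in clu.greedy_cluster(seqs, thr):
                assert cl.representative in cl.members
                assert all(
                    clu.pairwise_identity(by_id[m], by_id[cl.representative]) >= thr
                    for m in cl.members
                )
                assert len(by_id[cl.representative]) == max(
                    len(by_id[m]) for m in cl.members
                )


class TestClusterIncrease:
    def test_new_divergent_sequence_doubles_clusters(self):
        a = "MKVLDWERTG"
        b = "MKVLDWAAAA"  # identity 0.6 to a
        assert clu.cluster_increase([("a", a)], [("b", b)], 0.70) == pytest.approx(100.0)

    def test_identical_additions_add_nothing(self):
        base = [("a", "MKVLDWERTA"), ("b", "WWDERTNPQS")]
        added = [("c", "MKVLDWERTA")]
        assert clu.cluster_increase(base, added, 0.90) == pytest.approx(0.0)

    def test_matches_brute_force_recount(self, rng):
        base = _rand_seqs(rng, 20, 6, 25)
        added = [(f"n{i}", s) for i, (_, s) in enumerate(_rand_seqs(rng, 10, 6, 25))]
        for thr in (0.5, 0.9):
            n_base = len(brute_force_greedy_clusters(base, thr, clu.pairwise_identity))
            n_union = len(
                brute_force_greedy_clusters(base + added, thr, clu.pairwise_identity)
            )
            expected = 100.0 * (n_union - n_base) / n_base
            assert clu.cluster_increase(base, added, thr) == pytest.approx(expected)

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            clu.cluster_increase([], [("a", "MKVLD")], 0.5)

    def test_length_filter_applies_to_both_sets(self):
        base = [("a", "MKVLDWERTA"), ("tiny", "MK")]
        added = [("b", "MK")]
        assert clu.cluster_increase(base, added, 0.5, min_len_aa=5) == pytest.approx(0.0)


class TestAlignmentDiversity:
    def test_identical_rows(self):
        aln = SeedAlignment("f", [("a", "MKVLD"), ("b", "MKVLD")])
        ident, ents = clu.alignment_diversity(aln)
        assert ident == pytest.approx(1.0)
        np.testing.assert_allclose(ents, 0.0)

    def test_half_split_column_entropy_ln2(self):
        aln = SeedAlignment(
            "f", [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")]
        )
        _, ents = clu.alignment_diversity(aln)
        assert ents[0] == pytest.approx(np.log(2))

    def test_single_row_identity_absent_entropy_present(self):
        aln = SeedAlignment("f", [("a", "MKV")])
        ident, ents = clu.alignment_diversity(aln)
        assert ident is None
        assert len(ents) == 3

    def test_matches_direct_summation(self, rng):
        rows = []
        for i in range(5):
            chars = [
                "-" if rng.random() < 0.2 else AA[rng.integers(20)] for _ in range(12)
            ]
            rows.append((f"r{i}", "".join(chars)))
        # ensure no all-gap column ambiguity in the oracle comparison
        aln = SeedAlignment("f", rows)
        ident, ents = clu.alignment_diversity(aln)

        idents = []
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = rows[i][1], rows[j][1]
                pairs = [(x, y) for x, y in zip(a, b) if (x, y) != ("-", "-")]
                same = sum(1 for x, y in pairs if x == y and x != "-")
                idents.append(same / len(pairs))
        assert ident == pytest.approx(np.mean(idents))

        expected_ents = []
        for c in range(12):
            col = [r[1][c] for r in rows if r[1][c] != "-"]
            if not col:
                continue
            freqs = np.array([col.count(ch) for ch in sorted(set(col))]) / len(col)
            expected_ents.append(-(freqs * np.log(freqs)).sum())
        np.testing.assert_allclose(ents, expected_ents, atol=1e-12)
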