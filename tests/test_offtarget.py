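import numpy as np
import pytest

from canesacc.offtarget import (
    HairpinSpec,
    cds_window,
    count_shared_kmers,
    longest_shared_stretch,
    reverse_complement,
    screen_hairpin,
)


def dp_longest_common_substring(q: str, s: str) -> int:
    """O(nm) dynamic-programming oracle (N and non-ACGT never match)."""

    def clean(seq, bad):
        seq = seq.upper().replace("U", "T")
        return [c if c in "ACGT" else bad for c in seq]

    qa = np.array(clean(q, "!"), dtype="U1")
    sa = np.array(clean(s, "?"), dtype="U1")
    if len(qa) == 0 or len(sa) == 0:
        return 0
    best = 0
    prev = np.zeros(len(sa), dtype=np.int32)
    for ch in qa:
        eq = (sa == ch).astype(np.int32)
        cur = eq.copy()
        cur[1:] += eq[1:] * prev[:-1]
        best = max(best, int(cur.max()))
        prev = cur
    return best


def dp_both_strands(q: str, s: str) -> int:
    return max(dp_longest_common_substring(q, s),
               dp_longest_common_substring(q, reverse_complement(s)))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCdsWindow:
    def test_published_window_length(self):
        rng = np.random.default_rng(0)
        cds = random_seq(rng, 1300)
        assert len(cds_window(cds, 825, 1237)) == 413

    def test_single_position_window(self):
        assert cds_window("ACGT", 3, 3) == "G"

    def test_length_identity_for_random_windows(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 500)
        for _ in range(100):
            a = int(rng.integers(1, 500))
            b = int(rng.integers(a, 501))
            assert len(cds_window(seq, a, b)) == b - a + 1

    @pytest.mark.parametrize("start, end", [(0, 10), (5, 3), (1, 501)])
    def test_out_of_bounds_rejected(self, start, end):
        with pytest.raises(ValueError):
            cds_window("A" * 500, start, end)

    def test_hairpin_spec_extracts_window(self):
        rng = np.random.default_rng(2)
        cds = random_seq(rng, 1300)
        hp = HairpinSpec("CDS1", cds, 825, 1237)
        assert hp.target_sequence == cds[824:1237]
        assert len(hp) == 413


class TestLongestSharedStretch:
    def test_identical_sequences_match_fully(self):
        rng = np.random.default_rng(3)
        q = random_seq(rng, 413)
        hit = longest_shared_stretch(q, q)
        assert hit.length == 413
        assert (hit.query_start, hit.query_end) == (1, 413)
        assert (hit.subject_start, hit.subject_end) == (1, 413)

    def test_disjoint_alphabets_share_nothing(self):
        hit = longest_shared_stretch("A" * 50, "C" * 50)
        assert hit.length == 0

    def test_planted_stretch_lengths_recovered(self):
        from canesacc.simulate import simulate_offtarget_set

        query, subjects, truth = simulate_offtarget_set(
            planted_lengths=(24, 16, 15, 14, 13, 10), seed=11
        )
        for (sid, subject), (_, row) in zip(subjects, truth.iterrows()):
            hit = longest_shared_stretch(query, subject)
            assert hit.length == row["expected_longest_stretch"]
            assert hit.length == dp_both_strands(query, subject)

    def test_agrees_with_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for i in range(150):
            nq = int(rng.integers(1, 301))
            ns = int(rng.integers(1, 301))
            q, s = random_seq(rng, nq), random_seq(rng, ns)
            if i % 5 == 0:  # plant a shared block sometimes
                L = int(rng.integers(5, 30))
                if L <= min(nq, ns):
                    start_q = int(rng.integers(0, nq - L + 1))
                    start_s = int(rng.integers(0, ns - L + 1))
                    s = s[:start_s] + q[start_q:start_q + L] + s[start_s + L:]
            fast = longest_shared_stretch(q, s).length
            assert fast == dp_both_strands(q, s)

    def test_symmetry_of_length(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            q, s = random_seq(rng, 120), random_seq(rng, 150)
            assert (longest_shared_stretch(q, s).length
                    == longest_shared_stretch(s, q).length)

    def test_monotone_under_subject_extension(self):
        rng = np.random.default_rng(10)
        q = random_seq(rng, 200)
        s = random_seq(rng, 100)
        base = longest_shared_stretch(q, s).length
        extended = longest_shared_stretch(q, s + random_seq(rng, 300)).length
        assert extended >= base

    def test_reported_coordinates_point_at_equal_substrings(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            q, s = random_seq(rng, 150), random_seq(rng, 200)
            L = int(rng.integers(8, 25))
            qs = int(rng.integers(0, 150 - L + 1))
            ss = int(rng.integers(0, 200 - L + 1))
            s = s[:ss] + q[qs:qs + L] + s[ss + L:]
            hit = longest_shared_stretch(q, s)
            q_sub = q[hit.query_start - 1:hit.query_end]
            s_sub = s[hit.subject_start - 1:hit.subject_end]
            if hit.strand == "-":
                s_sub = reverse_complement(s_sub)
            assert q_sub == s_sub
            assert len(q_sub) == hit.length

    def test_reverse_strand_match_found_and_mapped(self):
        rng = np.random.default_rng(14)
        q = random_seq(rng, 100)
        insert = reverse_complement(q[40:70])
        s = random_seq(rng, 60) + insert + random_seq(rng, 60)
        hit = longest_shared_stretch(q, s)
        assert hit.length >= 30
        assert hit.strand == "-"
        assert reverse_complement(s[hit.subject_start - 1:hit.subject_end]) in q
        assert longest_shared_stretch(q, s, both_strands=False).length < 30

    def test_n_never_matches_even_itself(self):
        hit = longest_shared_stretch("ANNNA", "ANNNA", both_strands=False)
        assert hit.length == 1  # only the single A runs match

    def test_case_and_uracil_insensitive(self):
        hit = longest_shared_stretch("acguacgu", "ACGTACGT", both_strands=False)
        assert hit.length == 8

    def test_empty_sequence_gives_zero_hit(self):
        assert longest_shared_stretch("", "ACGT").length == 0
        assert longest_shared_stretch("ACGT", "").length == 0

    def test_snp_annotation_within_stretch(self):
        rng = np.random.default_rng(15)
        q = random_seq(rng, 100)
        s = random_seq(rng, 50) + q[10:40] + random_seq(rng, 50)
        hit = longest_shared_stretch(
            q, s, both_strands=False,
            variants=[(55, "A", "G"), (5, "C", "T"), (130, "G", "A")],
        )
        assert hit.subject_start == 51 and hit.subject_end == 80
        assert hit.snps_in_stretch == [(55, "A", "G")]


class TestCountSharedKmers:
    def test_self_comparison_counts_every_distinct_kmer(self):
        rng = np.random.default_rng(16)
        q = random_seq(rng, 413)
        distinct = len({q[i:i + 21] for i in range(413 - 21 + 1)})
        assert count_shared_kmers(q, q, k=21) == distinct
        assert distinct == 393  # this seed has no repeated 21-mer

    def test_single_planted_kmer(self):
        rng = np.random.default_rng(17)
        while True:
            q = random_seq(rng, 100)
            s = random_seq(rng, 200)
            if count_shared_kmers(q, s, k=21) == 0:
                break
        s2 = s[:90] + q[30:51] + s[90:]
        assert count_shared_kmers(q, s2, k=21) == 1

    def test_matches_naive_substring_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(30):
            q, s = random_seq(rng, 80), random_seq(rng, 120)
            L = int(rng.integers(4, 12))
            s = s[:40] + q[10:10 + L + 6] + s[40:]
            for k in (4, 6):
                rc = reverse_complement(s)
                naive = sum(
                    1
                    for km in {q[i:i + k] for i in range(len(q) - k + 1)}
                    if km in s or km in rc
                )
                assert count_shared_kmers(q, s, k=k) == naive

    def test_shared_stretch_implies_kmer_count_floor(self):
        rng = np.random.default_rng(19)
        q = random_seq(rng, 300)
        L = 40
        s = random_seq(rng, 100) + q[50:50 + L] + random_seq(rng, 100)
        k = 21
        assert count_shared_kmers(q, s, k=k) >= L - k + 1

    def test_oversized_k_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert count_shared_kmers("ACGT", "ACGT", k=10) == 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            count_shared_kmers("ACGT", "ACGT", k=0)


class TestScreenHairpin:
    def test_ranking_follows_planted_lengths(self):
        from canesacc.simulate import simulate_offtarget_set

        query, subjects, truth = simulate_offtarget_set(
            planted_lengths=(24, 16, 15), seed=20
        )
        cds = "G" * 824 + query + "G" * 100  # place query at window 825-1237
        hairpin = HairpinSpec("SYN_BAHD01", cds, 825, 825 + len(query) - 1)
        hits = screen_hairpin(hairpin, subjects)
        assert [h.length for h in hits] == [24, 16, 15]
        assert hits[0].subject_id == truth.iloc[0]["subject_id"]

    def test_source_cds_ranks_first_with_full_length_stretch(self):
        rng = np.random.default_rng(21)
        cds = random_seq(rng, 1300)
        hairpin = HairpinSpec("SRC", cds, 825, 1237)
        subjects = [("SRC_CDS", cds), ("OTHER", random_seq(rng, 1300))]
        hits = screen_hairpin(hairpin, subjects)
        assert hits[0].subject_id == "SRC_CDS"
        assert hits[0].length == 413

    def test_empty_subject_set_gives_empty_report(self):
        hairpin = HairpinSpec("SRC", "ACGTACGTACGT", 1, 8)
        assert screen_hairpin(hairpin, []) == []

    def test_duplicate_ids_rejected(self):
        hairpin = HairpinSpec("SRC", "ACGTACGTACGT", 1, 8)
        with pytest.raises(ValueError, match="duplicate"):
            screen_hairpin(hairpin, [("a", "ACGT"), ("a", "ACGT")])
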