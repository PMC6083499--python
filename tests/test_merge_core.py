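"""Seed anchoring, overlap scanning, acceptance thresholds and consensus."""

import numpy as np
import pytest

from barmerge.io_seq import Read, ReadPair, reverse_complement
from barmerge.merge_core import (
    STATUS_LOW_IDENTITY,
    STATUS_MERGED,
    STATUS_NO_SEED,
    STATUS_SHORT_OVERLAP,
    STATUS_TOO_MANY_GAPS,
    MergeParams,
    OverlapAnchor,
    OverlapScore,
    accept,
    build_consensus,
    find_anchor,
    merge_pair,
    scan_overlap,
)

from _oracles import (
    edlib_counts,
    make_overlap_instance,
    make_pair_with_overlap,
    random_seq,
    shares_kmer,
)

P = MergeParams()


def _flat(seq, q=40, name="x"):
    return Read(name, seq, [q] * len(seq))


class TestFindAnchor:
    def test_shared_suffix_prefix(self, rng):
        s = random_seq(rng, 16)
        fwd = _flat(random_seq(rng, 60) + s)
        rev = _flat(s + random_seq(rng, 60))
        a = find_anchor(fwd, rev, P)
        assert a is not None
        assert a.seed_start_fwd == 60 and a.seed_start_rev == 0
        assert fwd.seq[a.seed_start_fwd : a.seed_start_fwd + 16] == \
            rev.seq[a.seed_start_rev : a.seed_start_rev + 16]

    def test_no_common_16mer_gives_none(self, rng):
        while True:
            f, r = random_seq(rng, 100), random_seq(rng, 100)
            if not shares_kmer(f, r, 16):
                break
        assert find_anchor(_flat(f), _flat(r), P) is None

    def test_read_shorter_than_seed(self, rng):
        assert find_anchor(_flat("ACGTACGT"), _flat(random_seq(rng, 50)), P) is None

    def test_duplicate_seed_takes_leftmost_occurrence(self, rng):
        s = random_seq(rng, 16)
        fwd = _flat(random_seq(rng, 40) + s)
        rev = _flat(random_seq(rng, 10) + s + random_seq(rng, 30) + s)
        while shares_kmer(fwd.seq[:40], rev.seq, 16):  # keep the seed unique
            rev = _flat(random_seq(rng, 10) + s + random_seq(rng, 30) + s)
        a = find_anchor(fwd, rev, P)
        occurrences = [i for i in range(len(rev.seq) - 15)
                       if rev.seq[i : i + 16] == s]
        assert len(occurrences) == 2
        assert a.seed_start_rev == min(occurrences)

    def test_seed_slides_inward_by_step(self, rng):
        # Only a 16-mer ending 12 bp before the forward 3' end is shared.
        core = random_seq(rng, 16)
        fwd = _flat(random_seq(rng, 40) + core + random_seq(rng, 12))
        rev = _flat(core + random_seq(rng, 50))
        while shares_kmer(fwd.seq[-16:], rev.seq, 16):
            fwd = _flat(fwd.seq[:-12] + random_seq(rng, 12))
        a = find_anchor(fwd, rev, P)
        assert a is not None and a.seed_start_fwd == 40


class TestScanOverlap:
    def test_perfect_overlap(self, rng):
        fwd, rev, anchor, *_ = make_overlap_instance(rng, 30, 0, 0)
        score, aln = scan_overlap(fwd, rev, anchor, P)
        assert (score.identity_count, score.mismatch_count,
                score.gap_openings, score.overlap_columns) == (30, 0, 0, 30)

    def test_single_substitution_counts_one_mismatch(self, rng):
        fwd, rev, anchor, *_ = make_overlap_instance(rng, 40, 1, 0)
        score, _ = scan_overlap(fwd, rev, anchor, P)
        assert score.mismatch_count == 1 and score.gap_openings == 0
        assert score.overlap_columns == 40

    def test_single_insertion_is_one_gap_at_the_site(self, rng):
        for _ in range(20):
            fwd, rev, anchor, template, mutated = make_overlap_instance(rng, 50, 0, 1)
            score, aln = scan_overlap(fwd, rev, anchor, P)
            assert score.mismatch_count == 0
            assert score.gap_openings == 1
            assert score.overlap_columns == max(len(template), len(mutated))
            assert edlib_counts(template, mutated) == (0, 1)
            # the single gap column sits where the copies diverge
            gap_cols = [k for k, (fi, rj) in enumerate(aln.columns)
                        if fi is None or rj is None]
            assert len(gap_cols) == 1
            diverge = next(i for i in range(min(len(template), len(mutated)))
                           if template[i] != mutated[i])
            assert abs(gap_cols[0] - diverge) <= 1

    @pytest.mark.parametrize("n_subs,n_indels", [(0, 0), (1, 0), (2, 0),
                                                 (0, 1), (1, 1), (2, 1)])
    def test_counts_equal_dp_oracle(self, rng, n_subs, n_indels):
        for _ in range(25):
            length = int(rng.integers(40, 61))
            fwd, rev, anchor, template, mutated = make_overlap_instance(
                rng, length, n_subs, n_indels)
            score, _ = scan_overlap(fwd, rev, anchor, P)
            assert (score.mismatch_count, score.gap_openings) == \
                edlib_counts(template, mutated)

    def test_gap_rollback_charges_plain_mismatch(self, rng):
        # Two substitutions closer together than the tolerance: the
        # look-ahead after the first one fails, no gap placement can make
        # it pass, and the site must be rolled back to a plain mismatch.
        for _ in range(10):
            template = random_seq(rng, 30)
            mutated = list(template)
            for p in (12, 15):
                mutated[p] = [b for b in "ACGT" if b != mutated[p]][0]
            mutated = "".join(mutated)
            fwd = _flat(random_seq(rng, 10) + template)
            rev = _flat(mutated + random_seq(rng, 10))
            score, _ = scan_overlap(fwd, rev, OverlapAnchor(10, 0, 8), P)
            # a spurious self-similarity could legitimise a gap; require
            # the outcome to be no worse than two plain substitutions
            assert score.mismatch_count == 2
            assert score.gap_openings == 0
            assert score.overlap_columns == 30


class TestAccept:
    @pytest.mark.parametrize(
        "columns,identity,gaps,expected",
        [
            (20, 20, 0, STATUS_SHORT_OVERLAP),   # 100% identity, too short
            (189, 52, 4, STATUS_LOW_IDENTITY),   # long but ~27% identity
            (104, 43, 4, STATUS_LOW_IDENTITY),   # ~41% identity
            (30, 27, 5, None),                   # 90% / 5 gaps: inclusive accept
            (25, 25, 0, None),                   # boundary overlap length
            (30, 27, 6, STATUS_TOO_MANY_GAPS),
        ],
    )
    def test_threshold_logic(self, columns, identity, gaps, expected):
        score = OverlapScore(identity, columns - identity - gaps, gaps, columns)
        ok, reason = accept(score, P)
        assert reason == expected and ok == (expected is None)


class TestConsensus:
    def _merge_two(self, a, qa, b, qb):
        """One-column disagreement embedded in a perfect 30 bp overlap."""
        rng = np.random.default_rng(99)
        left = random_seq(rng, 15)
        right = random_seq(rng, 14)
        fwd = Read("f", "GATTACAGATTACA" + left + a + right, [40] * 14 + [40] * 15 + [qa] + [40] * 14)
        rev = Read("r", left + b + right + "TTGACATTGACATT",
                   [40] * 15 + [qb] + [40] * 14 + [40] * 14)
        anchor = OverlapAnchor(14, 0, 15)
        score, aln = scan_overlap(fwd, rev, anchor, P)
        consensus = build_consensus(fwd, rev, aln, "c")
        return consensus.seq[14 + 15], consensus.quals[14 + 15]

    def test_higher_quality_base_wins(self):
        base, qual = self._merge_two("A", 40, "G", 10)
        assert (base, qual) == ("A", 40)
        base, qual = self._merge_two("A", 10, "G", 40)
        assert (base, qual) == ("G", 40)

    def test_quality_tie_prefers_forward_base(self):
        base, _ = self._merge_two("A", 30, "G", 30)
        assert base == "A"

    def test_n_defers_to_other_read(self):
        base, qual = self._merge_two("N", 2, "C", 30)
        assert (base, qual) == ("C", 30)
        base, _ = self._merge_two("C", 30, "N", 2)
        assert base == "C"

    def test_both_n_stays_n_with_max_quality(self):
        base, qual = self._merge_two("N", 5, "N", 9)
        assert (base, qual) == ("N", 9)

    def test_agreeing_bases_keep_max_quality(self):
        base, qual = self._merge_two("T", 12, "T", 37)
        assert (base, qual) == ("T", 37)


class TestMergePair:
    def test_zero_error_pairs_reconstruct_fragment(self, clean_sim):
        pairs, truth = clean_sim
        for pair, t in zip(pairs, truth.pairs):
            out = merge_pair(pair)
            assert out.status == STATUS_MERGED
            assert out.consensus.seq == t.fragment
            assert len(out.consensus) == t.frag_len

    def test_unrelated_reads_no_seed(self, rng):
        while True:
            f, r = random_seq(rng, 250), random_seq(rng, 250)
            if not shares_kmer(f, r, 16) and \
               not shares_kmer(f, reverse_complement(_flat(r)).seq, 16):
                break
        out = merge_pair(ReadPair(_flat(f), _flat(r)))
        assert out.status == STATUS_NO_SEED and out.consensus is None

    def test_empty_ish_read_is_no_seed(self, rng):
        out = merge_pair(ReadPair(_flat("ACGT"), _flat(random_seq(rng, 100))))
        assert out.status == STATUS_NO_SEED

    def test_table2_style_rejections(self, rng):
        # overlap 20 at 100% identity: long enough to anchor, too short to merge
        out = merge_pair(make_pair_with_overlap(rng, 20, 1.0))
        assert out.status == STATUS_SHORT_OVERLAP
        # true overlap 12 bp at ~91%: below the seed length, never anchors
        out = merge_pair(make_pair_with_overlap(rng, 12, 0.91))
        assert out.status == STATUS_NO_SEED
        # long overlaps at 27.3% and 40.9% identity: anchored but dissimilar
        for identity in (0.273, 0.409):
            out = merge_pair(make_pair_with_overlap(rng, 189, identity, read_len=250))
            assert out.status == STATUS_LOW_IDENTITY

    def test_orientation_fallback_merges_preoriented_pair(self, clean_sim):
        pairs, truth = clean_sim
        pair = pairs[0]
        # hand the merger an already-forward-sense reverse read
        preoriented = ReadPair(pair.forward, reverse_complement(pair.reverse))
        out = merge_pair(preoriented, MergeParams())
        assert out.status == STATUS_MERGED
        assert out.consensus.seq == truth.pairs[0].fragment

    def test_swap_symmetry(self, clean_sim):
        pairs, _ = clean_sim
        for pair in pairs[:10]:
            direct = merge_pair(pair)
            swapped = merge_pair(ReadPair(pair.reverse, pair.forward))
            assert direct.status == swapped.status == STATUS_MERGED
            assert reverse_complement(swapped.consensus).seq == direct.consensus.seq

    def test_merged_outputs_respect_thresholds(self, noisy_sim):
        pairs, _ = noisy_sim
        p = MergeParams(min_overlap=10)
        for pair in pairs:
            out = merge_pair(pair, p)
            if out.merged:
                assert out.score.overlap_columns >= p.min_overlap
                assert out.score.identity_fraction >= p.min_identity
                assert out.score.gap_openings <= p.max_gap_openings
                gap_cols = sum(1 for fi, rj in out.alignment.columns
                               if fi is None or rj is None)
                assert len(out.consensus) == (
                    len(pair.forward) + len(pair.reverse)
                    - out.score.overlap_columns + gap_cols
                )
                assert len(out.consensus) <= len(pair.forward) + len(pair.reverse)
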