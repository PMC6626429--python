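"""Canonical k-mer counting against a naive oracle, selection, subsampling,
matrix construction and the repeat-content diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidbin.fragmentation import chunk_assembly
from ploidbin.io import AssemblyRecord
from ploidbin.kmers import (build_matrix, count_genome_kmers, decode_kmer,
                            default_min_count, encode_kmer,
                            repeatmers_per_fragment_histogram,
                            select_repeat_kmers, subsample_vocabulary)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_canonical_counts(seqs, k: int) -> dict[str, int]:
    """Sliding-window oracle: canonicalize each ACGT-only window by hand."""
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) - set("ACGT"):
                continue
            canon = min(window, revcomp(window))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestCountGenomeKmers:
    def test_small_example_with_palindromes(self):
        # CGTA absorbs its reverse complement TACG; ACGT and GTAC are palindromic
        table = count_genome_kmers([AssemblyRecord("s", "ACGTACGTACGT")], k=4)
        assert table.to_dict() == {"ACGT": 3, "CGTA": 4, "GTAC": 2}

    def test_n_windows_skipped(self):
        table = count_genome_kmers([AssemblyRecord("s", "ACGNACG")], k=3)
        assert table.to_dict() == {"ACG": 2}

    @settings(max_examples=30, deadline=None)
    @given(seq=dna, k=st.integers(2, 8))
    def test_matches_naive_oracle(self, seq, k):
        got = count_genome_kmers([AssemblyRecord("s", seq)], k).to_dict() if seq else {}
        assert got == naive_canonical_counts([seq], k)

    @settings(max_examples=20, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=300), k=st.integers(2, 12))
    def test_invariant_under_reverse_complement(self, seq, k):
        fwd = count_genome_kmers([AssemblyRecord("s", seq)], k).to_dict()
        rev = count_genome_kmers([AssemblyRecord("s", revcomp(seq))], k).to_dict()
        assert fwd == rev

    def test_k_longer_than_every_scaffold(self, caplog):
        with caplog.at_level("WARNING"):
            table = count_genome_kmers([AssemblyRecord("s", "ACGT")], k=10)
        assert len(table) == 0

    def test_stranded_mode_keeps_orientation(self):
        table = count_genome_kmers([AssemblyRecord("s", "AAAC")], k=3, stranded=True)
        assert table.to_dict() == {"AAA": 1, "AAC": 1}

    def test_code_round_trip(self):
        for kmer in ("ACGT", "TTTT", "GATTACA"):
            assert decode_kmer(encode_kmer(kmer), len(kmer)) == kmer


class TestSelectRepeatKmers:
    def _table(self, counts: dict[str, int]):
        records = [AssemblyRecord(f"s{i}", kmer * n)
                   for i, (kmer, n) in enumerate(counts.items())]
        return count_genome_kmers(records, k=len(next(iter(counts))))

    def test_frequency_window_filter(self):
        table = count_genome_kmers(
            [AssemblyRecord("s", "AC" * 2 + "TT" * 150 + "GG" * 600)], k=2)
        vocab = select_repeat_kmers(table, min_count=100)
        kept = set(vocab.kmers)
        assert "CC" in kept or "GG" in kept  # canonical form of the G run
        assert "AC" not in kept and "GT" not in kept

    def test_vacuous_filter_keeps_all(self):
        table = count_genome_kmers([AssemblyRecord("s", "ACGTAC")], k=3)
        vocab = select_repeat_kmers(table, min_count=1)
        assert len(vocab) == len(table)

    def test_empty_vocabulary_is_fatal_with_guidance(self):
        table = count_genome_kmers([AssemblyRecord("s", "ACGTACGA")], k=4)
        with pytest.raises(ValueError, match="min_count"):
            select_repeat_kmers(table, min_count=1000)

    def test_vocabulary_is_lexicographic(self):
        table = count_genome_kmers([AssemblyRecord("s", "TTTTTTTTAAAAAAAACCCCCCCC")], k=3)
        vocab = select_repeat_kmers(table, min_count=1)
        assert vocab.kmers == sorted(vocab.kmers)

    def test_default_min_count_scaling(self):
        assert default_min_count(2_900_000_000) == 150
        assert default_min_count(4_000_000) == 3  # floored


class TestSubsampleVocabulary:
    def _vocab(self, n=10):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        table = count_genome_kmers([AssemblyRecord("s", seq * 3)], k=6)
        return select_repeat_kmers(table, min_count=1)

    def test_identity_when_target_equals_size(self):
        vocab = self._vocab()
        sub = subsample_vocabulary(vocab, len(vocab), seed=1)
        assert np.array_equal(sub.codes, vocab.codes)

    def test_reproducible_under_seed(self):
        vocab = self._vocab()
        a = subsample_vocabulary(vocab, len(vocab) // 2, seed=7)
        b = subsample_vocabulary(vocab, len(vocab) // 2, seed=7)
        assert np.array_equal(a.codes, b.codes)

    def test_different_seeds_differ(self):
        vocab = self._vocab()
        a = subsample_vocabulary(vocab, len(vocab) // 2, seed=1)
        b = subsample_vocabulary(vocab, len(vocab) // 2, seed=2)
        assert not np.array_equal(a.codes, b.codes)

    def test_oversized_target_returns_unchanged(self, caplog):
        vocab = self._vocab()
        with caplog.at_level("WARNING"):
            sub = subsample_vocabulary(vocab, len(vocab) + 5, seed=1)
        assert np.array_equal(sub.codes, vocab.codes)


class TestBuildMatrix:
    def test_tandem_repeat_counts(self):
        kmer = "ACGTTGCA"
        rec = AssemblyRecord("s", kmer * 5)
        fragments = chunk_assembly([rec], fragment_length=len(rec.sequence), min_length=1)
        vocab = select_repeat_kmers(count_genome_kmers([rec], k=len(kmer)), min_count=1)
        matrix = build_matrix(fragments, [rec], vocab)
        canon = min(kmer, revcomp(kmer))
        assert matrix.counts[0, vocab.kmers.index(canon)] >= 5

    def test_disjoint_vocabulary_gives_zero_row(self):
        recs = [AssemblyRecord("a", "AAAAAAAAAA"), AssemblyRecord("b", "GGGGGGGGGG")]
        fragments = chunk_assembly(recs, fragment_length=10, min_length=1)
        table = count_genome_kmers([recs[1]], k=4)
        vocab = select_repeat_kmers(table, min_count=1)
        matrix = build_matrix(fragments, recs, vocab)
        assert matrix.row_sums[0] == 0 and matrix.row_sums[1] > 0

    def test_row_sums_bounded_by_window_count(self, tobacco_run):
        matrix = tobacco_run.matrix
        bound = tobacco_run.fragments.lengths - matrix.vocab.k + 1
        assert np.all(matrix.row_sums <= bound)

    def test_column_sums_bounded_by_genome_counts(self, tobacco_run):
        col_sums = np.asarray(tobacco_run.matrix.counts.sum(axis=0)).ravel()
        assert np.all(col_sums <= tobacco_run.matrix.vocab.genome_counts)


class TestDiagnostics:
    def _matrix(self, seq_blocks, k=4, min_count=1):
        recs = [AssemblyRecord(f"s{i}", s) for i, s in enumerate(seq_blocks)]
        fragments = chunk_assembly(recs, fragment_length=max(len(s) for s in seq_blocks),
                                   min_length=1)
        vocab = select_repeat_kmers(count_genome_kmers(recs, k), min_count)
        return build_matrix(fragments, recs, vocab)

    def test_all_zero_matrix_triggers_recommendation(self):
        matrix = self._matrix(["AAAAAAAA", "CCCCCCCC"])
        matrix.counts = matrix.counts * 0
        diag = repeatmers_per_fragment_histogram(matrix)
        assert diag.zero_fraction == 1.0
        assert diag.recommend

    def test_histogram_of_single_row(self):
        matrix = self._matrix(["ACGTACG"])  # 4 windows of k=4
        diag = repeatmers_per_fragment_histogram(matrix)
        assert diag.histogram == {4: 1}

    def test_recommendation_threshold_on_median(self):
        matrix = self._matrix(["A" * 40, "C" * 40])
        low = repeatmers_per_fragment_histogram(matrix, recommend_floor=100)
        high = repeatmers_per_fragment_histogram(matrix, recommend_floor=10)
        assert low.recommend and not high.recommend
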