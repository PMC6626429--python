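"""Repeat k-mer selection and the sparse fragment x k-mer count matrix.

Repetitive k-mers act as natural molecular barcodes: transposon families
proliferate independently in the progenitors of an allopolyploid, so k-mers
that are frequent genome-wide but private to one subgenome identify the
subgenome of origin of the sequence that carries them.  This module selects
k-mers by genome-wide frequency and counts their occurrences per fragment.

K-mers are strand-collapsed to their canonical form (the lexicographic
minimum of a k-mer and its reverse complement) by default, because repeats
insert in both orientations; a ``stranded`` mode is available.  Internally
k-mers are 2-bit packed into uint64 codes (A=0, C=1, G=2, T=3), so the
numeric order of codes equals lexicographic order of the strings and the
vocabulary is deterministic across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import sparse

from .fragmentation import FragmentSet
from .io import AssemblyRecord

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_BASES = "ACGT"

MAX_K = 32  # 2 bits per base in a uint64


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(int(code) >> shift) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    codes = encode_sequence(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def window_codes(codes: np.ndarray, k: int,
                 stranded: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every length-k window of an encoded sequence.

    Returns ``(packed, valid)`` where ``packed[i]`` is the (canonical unless
    ``stranded``) code of the window starting at i and ``valid[i]`` is False
    when the window contains an N.
    """
    if not 2 <= k <= MAX_K:
        raise ValueError(f"k must be in [2, {MAX_K}], got {k}")
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_n = (codes == 4)
    bad = np.cumsum(np.concatenate(([0], is_n.astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    c = (codes & 3).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):  # k vectorized passes; O(k n) total
        fwd = (fwd << np.uint64(2)) | c[j : j + m]
    if stranded:
        return fwd, valid
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rev |= (np.uint64(3) - c[j : j + m]) << np.uint64(2 * j)
    return np.minimum(fwd, rev), valid


@dataclass
class KmerCountTable:
    """Genome-wide k-mer counts, code-sorted; behaves like a read-only map."""

    k: int
    codes: np.ndarray   # sorted uint64
    counts: np.ndarray  # int64, aligned with codes

    def __len__(self) -> int:
        return self.codes.size

    def get(self, kmer: str, default: int = 0) -> int:
        code = np.uint64(encode_kmer(kmer))
        i = int(np.searchsorted(self.codes, code))
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return default

    def __getitem__(self, kmer: str) -> int:
        value = self.get(kmer, -1)
        if value < 0:
            raise KeyError(kmer)
        return value

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer, -1) >= 0

    def items(self) -> Iterator[tuple[str, int]]:
        for code, count in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(count)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())


def count_genome_kmers(assembly: Sequence[AssemblyRecord], k: int,
                       stranded: bool = False) -> KmerCountTable:
    """Count every length-k window over the whole assembly.

    Windows containing N are skipped.  Counts are canonical (strand-collapsed)
    unless ``stranded``.
    """
    chunks: list[np.ndarray] = []
    for rec in assembly:
        packed, valid = window_codes(encode_sequence(rec.sequence), k, stranded)
        if packed.size:
            chunks.append(packed[valid])
    if not chunks or all(c.size == 0 for c in chunks):
        log.warning("k=%d longer than every scaffold (or all windows contain N)", k)
        return KmerCountTable(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerCountTable(k, codes, counts.astype(np.int64))


@dataclass
class KmerVocabulary:
    """Repeat k-mers retained by the genome-frequency filter, code-sorted
    (equivalently: lexicographically ordered)."""

    k: int
    codes: np.ndarray
    genome_counts: np.ndarray
    min_count: int
    max_count: int | None

    def __len__(self) -> int:
        return self.codes.size

    @property
    def kmers(self) -> list[str]:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for code, count in zip(self.codes, self.genome_counts):
                kmer = decode_kmer(int(code), self.k)
                fh.write(f">{kmer} count={int(count)}\n{kmer}\n")


def select_repeat_kmers(table: KmerCountTable, min_count: int,
                        max_count: int | None = None) -> KmerVocabulary:
    """Keep k-mers whose genome-wide count lies in [min_count, max_count]."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if max_count is not None and max_count < min_count:
        raise ValueError("max_count must be >= min_count")
    keep = table.counts >= min_count
    if max_count is not None:
        keep &= table.counts <= max_count
    if not keep.any():
        raise ValueError(
            "no k-mers pass the genome-frequency filter; lower min_count or "
            "decrease k to admit more repetitive k-mers"
        )
    return KmerVocabulary(table.k, table.codes[keep], table.counts[keep],
                          min_count, max_count)


def subsample_vocabulary(vocab: KmerVocabulary, target_size: int,
                         seed: int) -> KmerVocabulary:
    """Uniform sample without replacement, for vocabularies too large to hold.

    Reproducible under a fixed seed; requesting more than available returns
    the vocabulary unchanged with a warning.
    """
    if target_size >= len(vocab):
        if target_size > len(vocab):
            log.warning("subsample target %d > vocabulary size %d; keeping all",
                        target_size, len(vocab))
        return vocab
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(vocab), size=target_size, replace=False))
    return KmerVocabulary(vocab.k, vocab.codes[idx], vocab.genome_counts[idx],
                          vocab.min_count, vocab.max_count)


@dataclass
class RepeatKmerMatrix:
    """Sparse fragments x repeat-k-mers count matrix."""

    fragment_ids: list[str]
    vocab: KmerVocabulary
    counts: sparse.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def write_mtx(self, prefix) -> None:
        from scipy.io import mmwrite

        mmwrite(f"{prefix}.mtx", self.counts)
        with open(f"{prefix}.rows.txt", "w") as fh:
            fh.write("\n".join(self.fragment_ids) + "\n")
        with open(f"{prefix}.cols.txt", "w") as fh:
            fh.write("\n".join(self.vocab.kmers) + "\n")


def build_matrix(fragments: FragmentSet, assembly: Sequence[AssemblyRecord],
                 vocab: KmerVocabulary, stranded: bool = False,
                 log1p: bool = False) -> RepeatKmerMatrix:
    """Exact per-fragment occurrence counts of the vocabulary k-mers.

    Windows are counted within each fragment's own sequence (windows
    straddling fragment boundaries belong to neither side), so row sums are
    bounded by ``fragment_length - k + 1``.  All-zero rows are retained: such
    fragments become "ambiguous" downstream.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    seqs = {rec.scaffold_id: rec.sequence for rec in assembly}
    scaffold_codes = {sid: encode_sequence(s) for sid, s in seqs.items()}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for i, frag in enumerate(fragments.fragments):
        codes = scaffold_codes[frag.scaffold_id][frag.start : frag.end]
        packed, valid = window_codes(codes, vocab.k, stranded)
        packed = packed[valid]
        if packed.size == 0:
            continue
        pos = np.searchsorted(vocab.codes, packed)
        inside = pos < vocab.codes.size
        pos = pos[inside]
        hit = vocab.codes[pos] == packed[inside]
        if not hit.any():
            continue
        col_counts = np.bincount(pos[hit], minlength=len(vocab))
        nz = np.nonzero(col_counts)[0]
        rows.append(np.full(nz.size, i, dtype=np.int64))
        cols.append(nz)
        data.append(col_counts[nz])
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(fragments), len(vocab)), dtype=np.float64,
        ).tocsr()
    else:
        mat = sparse.csr_matrix((len(fragments), len(vocab)), dtype=np.float64)
    if log1p:
        mat = mat.copy()
        mat.data = np.log1p(mat.data)
    return RepeatKmerMatrix(fragments.fragment_ids, vocab, mat)


@dataclass
class RepeatmerDiagnostics:
    """Row-sum distribution of the count matrix, used as a parameter check."""

    row_sums: np.ndarray
    zero_fraction: float
    median: float
    recommend_floor: int
    recommend: bool
    histogram: dict[int, int]

    @property
    def message(self) -> str:
        if not self.recommend:
            return "repeat-mer content per fragment looks sufficient"
        return (
            f"median repeat-mers per fragment is {self.median:.0f} "
            f"(< {self.recommend_floor}); consider decreasing k, increasing "
            "fragment length, or lowering min_count to raise repetitive "
            "content per fragment"
        )


def repeatmers_per_fragment_histogram(matrix: RepeatKmerMatrix,
                                      recommend_floor: int = 30) -> RepeatmerDiagnostics:
    """Distribution of repeat-mers per fragment.

    A distribution skewed to low counts means fragments carry too little
    repetitive signal to bin confidently; the recommendation fires when the
    median row sum falls below ``recommend_floor``.
    """
    row_sums = matrix.row_sums.astype(np.int64)
    zero_fraction = float((row_sums == 0).mean()) if row_sums.size else 1.0
    median = float(np.median(row_sums)) if row_sums.size else 0.0
    values, freqs = np.unique(row_sums, return_counts=True)
    diag = RepeatmerDiagnostics(
        row_sums=row_sums,
        zero_fraction=zero_fraction,
        median=median,
        recommend_floor=recommend_floor,
        recommend=median < recommend_floor,
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
    )
    if diag.recommend:
        log.warning("%s", diag.message)
    return diag


def default_min_count(genome_bp: int, reference_bp: float = 2.9e9,
                      reference_threshold: int = 150, floor: int = 3) -> int:
    """Scale the repeat-k-mer frequency threshold with genome size.

    A 2.9 Gb genome pairs with a threshold of 150; smaller genomes get a
    proportionally lower threshold, floored at 3.
    """
    return max(floor, round(genome_bp / reference_bp * reference_threshold))
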