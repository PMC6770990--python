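"""Canonical k-mer counting and the k-mer depth histogram.

Counts every window of k consecutive A/C/G/T bases in a read set under its
canonical form -- the lexicographic minimum of the k-mer and its reverse
complement, the same convention as ``jellyfish count -C`` -- and aggregates
distinct k-mers by their depth (number of occurrences) into the spectrum
that genome profiling interprets.

Windows containing any non-ACGT symbol are skipped rather than substituted.
Input is case-insensitive; U is treated as invalid (DNA only).  Internally
k-mers are packed into 2-bit codes (k <= 31 fits a uint64) and counted by a
sort/run-length pass, which keeps a 100-Mbp read set comfortably in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import EmptyHistogramError, GenoprofError, ParseError
from .util import encode_seq

__all__ = [
    "KmerHistogram",
    "KmerCountTable",
    "count_table",
    "count_canonical_kmers",
    "merge_count_tables",
    "merge_histograms",
    "read_histogram",
    "write_histogram",
]

DEFAULT_MAX_DEPTH_BIN = 10_000
_CHUNK = 1 << 23  # window positions processed per vectorized pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class KmerHistogram:
    """The k-mer depth spectrum: ``freq[c]`` is the number of distinct
    canonical k-mers observed exactly ``c`` times.

    ``total_bases`` (T) and ``mean_read_length`` (L) are carried alongside
    the spectrum because genome-size estimation needs them; they are zero
    when the histogram was read from a bare text file.  Depths above
    ``max_depth_bin`` accumulate in that overflow bin.
    """

    k: int
    freq: dict[int, int]
    total_bases: int = 0
    mean_read_length: float = 0.0
    max_depth_bin: int = DEFAULT_MAX_DEPTH_BIN

    @property
    def total_kmers(self) -> int:
        """Sum of c * freq[c]: the number of counted k-mer instances
        (exact as long as no depth overflowed ``max_depth_bin``)."""
        return sum(c * n for c, n in self.freq.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.freq.values())

    @property
    def max_depth(self) -> int:
        return max(self.freq) if self.freq else 0


@dataclass(eq=False)
class KmerCountTable:
    """Per-k-mer counts: sorted unique canonical 2-bit codes with their
    depths.  This is the mergeable representation -- histograms of
    non-disjoint k-mer sets cannot be merged, count tables always can."""

    k: int
    codes: np.ndarray
    counts: np.ndarray
    total_bases: int
    n_reads: int
    mean_read_length: float

    def histogram(self, max_depth_bin: int = DEFAULT_MAX_DEPTH_BIN) -> KmerHistogram:
        clipped = np.minimum(self.counts, max_depth_bin)
        bc = np.bincount(clipped)
        freq = {int(c): int(n) for c, n in enumerate(bc) if n and c > 0}
        return KmerHistogram(
            k=self.k,
            freq=freq,
            total_bases=self.total_bases,
            mean_read_length=self.mean_read_length,
            max_depth_bin=max_depth_bin,
        )


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _canonical_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical uint64 codes of all valid k-windows of a 1-D uint8 code
    array in which 4 marks invalid bases and read separators.

    Window codes are assembled by binary doubling -- blocks of 1, 2, 4, ...
    bases are combined pairwise -- so the work is O(n log k) vector passes
    rather than O(n k).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    c = (codes & 3).astype(np.uint64)
    bad_cum = np.zeros(codes.size + 1, dtype=np.int32)
    np.cumsum(codes > 3, out=bad_cum[1:])
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0

    # binary decomposition of k, largest block first
    blocks: list[int] = []
    s = 1
    while s * 2 <= k:
        s *= 2
    rem = k
    while s >= 1:
        if rem >= s:
            blocks.append(s)
            rem -= s
        s //= 2
    need = set(blocks)

    # build doubling levels, keeping only the ones the decomposition uses
    # (holding every level alive churns hundreds of MB per chunk)
    keep: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    f, r = c, np.uint64(3) ^ c
    size = 1
    if size in need:
        keep[size] = (f, r)
    while size * 2 <= k:
        m = f.size - size
        f2 = (f[:m] << np.uint64(2 * size)) | f[size : size + m]
        r2 = (r[size : size + m] << np.uint64(2 * size)) | r[:m]
        f, r, size = f2, r2, size * 2
        if size in need:
            keep[size] = (f, r)

    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    offset = 0
    for bs in blocks:
        fseg, rseg = keep[bs]
        fwd = (fwd << np.uint64(2 * bs)) | fseg[offset : offset + n]
        # in the reverse complement, the block at base offset ``offset``
        # lands above the 2*offset low-order bits
        rc |= rseg[offset : offset + n] << np.uint64(2 * offset)
        offset += bs
    return np.minimum(fwd, rc)[valid]


def _concat_codes(reads) -> tuple[np.ndarray, int, int]:
    """Flatten a read collection into one uint8 code array with separator
    symbols (4) between reads; returns (codes, total_bases, n_reads)."""
    if hasattr(reads, "r1") and hasattr(reads, "r2"):  # simulator ReadSet
        mats = []
        for mat in (reads.r1, reads.r2):
            padded = np.full((mat.shape[0], mat.shape[1] + 1), 4, dtype=np.uint8)
            padded[:, :-1] = mat
            mats.append(padded.reshape(-1))
        return np.concatenate(mats), reads.total_bases, reads.n_reads
    parts: list[np.ndarray] = []
    total = n = 0
    sep = np.array([4], dtype=np.uint8)
    for seq in reads:
        enc = encode_seq(seq)
        parts.append(enc)
        parts.append(sep)
        total += len(seq)
        n += 1
    if not parts:
        raise EmptyHistogramError("read collection is empty")
    return np.concatenate(parts), total, n


def count_table(reads, k: int) -> KmerCountTable:
    """Count canonical k-mers in a read collection (an iterable of strings,
    or a simulator ``ReadSet``) into a per-k-mer count table."""
    if k < 1:
        raise GenoprofError(f"k must be >= 1, got {k}")
    if k > 31:
        raise GenoprofError(f"k must be <= 31 to fit 2-bit packing, got {k}")
    codes, total_bases, n_reads = _concat_codes(reads)

    chunks: list[np.ndarray] = []
    for start in range(0, codes.size, _CHUNK):
        sub = codes[start : start + _CHUNK + k - 1]
        win = _canonical_window_codes(sub, k)
        if win.size:
            chunks.append(win)
    if not chunks:
        raise EmptyHistogramError(
            f"no valid {k}-mer window in {n_reads} read(s); "
            "k may exceed every read length"
        )
    allc = np.concatenate(chunks)
    chunks.clear()
    allc.sort()

    boundaries = np.flatnonzero(allc[1:] != allc[:-1])
    starts = np.concatenate([[0], boundaries + 1])
    counts = np.diff(np.concatenate([starts, [allc.size]]))
    uniq = allc[starts]
    mean_len = total_bases / n_reads if n_reads else 0.0
    return KmerCountTable(k, uniq, counts, total_bases, n_reads, mean_len)


def count_canonical_kmers(
    reads, k: int, max_depth_bin: int = DEFAULT_MAX_DEPTH_BIN
) -> KmerHistogram:
    """Count canonical k-mers and aggregate straight into a depth histogram."""
    return count_table(reads, k).histogram(max_depth_bin)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_count_tables(a: KmerCountTable, b: KmerCountTable) -> KmerCountTable:
    """Merge per-k-mer counts of two tables (the depths of shared k-mers
    add); equivalent to having counted both read collections as one."""
    if a.k != b.k:
        raise GenoprofError(f"cannot merge count tables with k={a.k} and k={b.k}")
    codes = np.concatenate([a.codes, b.codes])
    counts = np.concatenate([a.counts, b.counts])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    if codes.size:
        boundaries = np.flatnonzero(codes[1:] != codes[:-1])
        starts = np.concatenate([[0], boundaries + 1])
        merged_counts = np.add.reduceat(counts, starts)
        codes = codes[starts]
        counts = merged_counts
    n_reads = a.n_reads + b.n_reads
    total = a.total_bases + b.total_bases
    mean_len = total / n_reads if n_reads else 0.0
    return KmerCountTable(a.k, codes, counts, total, n_reads, mean_len)


def merge_histograms(h1: KmerHistogram, h2: KmerHistogram) -> KmerHistogram:
    """Add two histograms bin-wise.

    Histogram-level merging is only exact when the two inputs share no
    k-mer (e.g. spectra of different chromosomes of one assembly); for read
    files of one library, merge :class:`KmerCountTable` objects instead.
    Totals (T, distinct counts) are additive either way.
    """
    if h1.k != h2.k:
        raise GenoprofError(f"cannot merge histograms with k={h1.k} and k={h2.k}")
    freq = dict(h1.freq)
    for c, n in h2.freq.items():
        freq[c] = freq.get(c, 0) + n
    total = h1.total_bases + h2.total_bases
    if total:
        mean_len = (
            h1.mean_read_length * h1.total_bases + h2.mean_read_length * h2.total_bases
        ) / total
    else:
        mean_len = h1.mean_read_length or h2.mean_read_length
    return KmerHistogram(
        k=h1.k,
        freq=freq,
        total_bases=total,
        mean_read_length=mean_len,
        max_depth_bin=max(h1.max_depth_bin, h2.max_depth_bin),
    )


# ---------------------------------------------------------------------------
# histogram I/O ("depth count" text lines, the jellyfish-histo dialect)
# ---------------------------------------------------------------------------

def write_histogram(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(hist.freq):
            fh.write(f"{c} {hist.freq[c]}\n")


def read_histogram(
    path,
    k: int = 0,
    total_bases: int = 0,
    mean_read_length: float = 0.0,
    max_depth_bin: int = DEFAULT_MAX_DEPTH_BIN,
) -> KmerHistogram:
    """Parse whitespace-separated ``depth count`` lines, ascending depth.

    The text format carries neither k nor the read-set totals; pass them
    explicitly when the downstream profile needs them.
    """
    freq: dict[int, int] = {}
    prev = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'depth count', got {stripped!r}"
                )
            try:
                depth, count = int(fields[0]), int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer field in {stripped!r}"
                ) from None
            if depth < 1 or count < 0:
                raise ParseError(
                    f"{path}: line {lineno}: depth must be >= 1 and count >= 0"
                )
            if depth <= prev:
                raise ParseError(
                    f"{path}: line {lineno}: depths must be strictly ascending"
                )
            prev = depth
            if count:
                freq[depth] = count
    return KmerHistogram(
        k=k,
        freq=freq,
        total_bases=total_bases,
        mean_read_length=mean_read_length,
        max_depth_bin=max_depth_bin,
    )
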