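"""Assembly contiguity and gap statistics.

Computes the standard descriptive statistics of a contig- or
scaffold-level assembly: Nx for x in 1..100 (N50 in particular), L50,
cumulative length curves, GC content over non-N bases, gapped/ungapped
lengths, the decomposition of scaffolds into contigs at N-gap runs, and
the fraction of the assembly held in records above size thresholds.

Sequences themselves are reduced on ingestion to per-record lengths and
N-run intervals plus set-level base tallies, so multi-Gbp assemblies
stream through without being held in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .util import round_half_up, xopen

__all__ = [
    "SequenceRecordStats",
    "SequenceSet",
    "ContiguityStats",
    "sequence_set_from_records",
    "sequence_set_from_fasta",
    "split_scaffolds",
    "nx",
    "l50",
    "nx_curve",
    "summarize",
    "cumulative_curve",
    "ungapped_percent",
]

DEFAULT_MIN_GAP_RUN = 10  # NCBI convention: >= 10 consecutive N = assembly gap
DEFAULT_THRESHOLDS = (100_000, 1_000_000)


@dataclass
class SequenceRecordStats:
    """Length and N-run intervals (0-based half-open, sorted, disjoint) of
    one sequence record."""

    id: str
    length: int
    n_run_intervals: list[tuple[int, int]]

    @property
    def n_bases(self) -> int:
        return sum(e - s for s, e in self.n_run_intervals)


@dataclass
class SequenceSet:
    """Reduced representation of an assembly: per-record stats plus
    set-level GC and ambiguity tallies (GC is tracked at set level because
    splitting scaffolds cannot re-apportion it without the sequences)."""

    records: list[SequenceRecordStats]
    gc_bases: int = 0
    ambiguous_bases: int = 0  # IUPAC codes other than N; counted as non-GC non-N
    is_scaffold_level: bool = True

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def n_bases(self) -> int:
        return sum(r.n_bases for r in self.records)

    @property
    def lengths(self) -> list[int]:
        return [r.length for r in self.records]


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def sequence_set_from_records(
    items: Iterable[tuple[str, str]], is_scaffold_level: bool = True
) -> SequenceSet:
    """Build a :class:`SequenceSet` from (id, sequence) pairs."""
    records: list[SequenceRecordStats] = []
    gc = ambig = 0
    for name, seq in items:
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_gc = (raw == ord("G")) | (raw == ord("C"))
        is_at = (raw == ord("A")) | (raw == ord("T"))
        is_n = raw == ord("N")
        gc += int(is_gc.sum())
        ambig += int(raw.size - is_gc.sum() - is_at.sum() - is_n.sum())
        records.append(SequenceRecordStats(name, int(raw.size), _runs_of(is_n)))
    return SequenceSet(records, gc, ambig, is_scaffold_level)


def sequence_set_from_fasta(path, is_scaffold_level: bool = True) -> SequenceSet:
    """Stream a (possibly gzipped) FASTA file into a :class:`SequenceSet`."""
    from Bio import SeqIO

    def _iter():
        with xopen(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)

    return sequence_set_from_records(_iter(), is_scaffold_level)


def split_scaffolds(
    seqs: SequenceSet, min_gap_run: int = DEFAULT_MIN_GAP_RUN
) -> SequenceSet:
    """Split every scaffold at each run of >= ``min_gap_run`` consecutive N.

    Shorter N runs stay inside the resulting contigs; empty fragments
    (e.g. from leading/trailing gaps or all-N records) are dropped.  The
    sum of contig lengths plus the removed gap bases equals the scaffold
    length.
    """
    if min_gap_run < 1:
        raise ValueError(f"min_gap_run must be >= 1, got {min_gap_run}")
    out: list[SequenceRecordStats] = []
    for rec in seqs.records:
        big = [(s, e) for s, e in rec.n_run_intervals if e - s >= min_gap_run]
        cuts = []
        prev = 0
        for s, e in big:
            cuts.append((prev, s))
            prev = e
        cuts.append((prev, rec.length))
        idx = 0
        for fs, fe in cuts:
            if fe <= fs:
                continue
            inner = [
                (s - fs, e - fs)
                for s, e in rec.n_run_intervals
                if s >= fs and e <= fe
            ]
            out.append(SequenceRecordStats(f"{rec.id}.{idx}", fe - fs, inner))
            idx += 1
    return SequenceSet(out, seqs.gc_bases, seqs.ambiguous_bases, is_scaffold_level=False)


# ---------------------------------------------------------------------------
# Nx / L50
# ---------------------------------------------------------------------------

def _sorted_cumsum(lengths) -> tuple[np.ndarray, np.ndarray]:
    ls = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if ls.size == 0:
        raise ValueError("empty length set")
    return ls, np.cumsum(ls)


def nx(lengths, x: float) -> int:
    """Length of the record at which the cumulative sum of
    descending-sorted lengths first reaches x% of the total (ties
    included)."""
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    ls, cs = _sorted_cumsum(lengths)
    target = x / 100.0 * cs[-1]
    i = int(np.searchsorted(cs, target, side="left"))
    return int(ls[i])


def l50(lengths) -> int:
    """Number of records needed to reach 50% of the total length."""
    ls, cs = _sorted_cumsum(lengths)
    target = 0.5 * cs[-1]
    return int(np.searchsorted(cs, target, side="left")) + 1


def nx_curve(lengths) -> list[tuple[int, int]]:
    """(x, Nx) for x = 1..100; Nx is non-increasing in x."""
    ls, cs = _sorted_cumsum(lengths)
    xs = np.arange(1, 101)
    targets = xs / 100.0 * cs[-1]
    idx = np.searchsorted(cs, targets, side="left")
    return list(zip(xs.tolist(), ls[idx].tolist()))


def cumulative_curve(lengths) -> list[tuple[int, int]]:
    """(rank, cumulative bp) with records sorted largest first."""
    ls, cs = _sorted_cumsum(lengths)
    return list(zip(range(1, ls.size + 1), cs.tolist()))


def ungapped_percent(ungapped_bp: float, total_bp: float) -> float:
    """Ungapped share of the assembly, half-up rounded to 1 decimal as
    conventionally printed."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    return round_half_up(100.0 * ungapped_bp / total_bp, 1)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class ContiguityStats:
    """Whole-assembly contiguity and composition summary."""

    total_bp: int
    count: int
    max_bp: int
    mean_bp: float
    n50: int
    l50: int
    nx: dict[int, int]
    gc_percent: float
    ungapped_bp: int
    ungapped_percent: float
    frac_ge_thresholds: dict[int, float]
    is_scaffold_level: bool

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["nx"] = {str(k): v for k, v in self.nx.items()}
        d["frac_ge_thresholds"] = {
            str(k): v for k, v in self.frac_ge_thresholds.items()
        }
        return d


def summarize(
    seqs: SequenceSet, thresholds: Iterable[int] = DEFAULT_THRESHOLDS
) -> ContiguityStats:
    """Compute all contiguity statistics of a sequence set.

    GC is computed over non-N bases only (other ambiguity codes count as
    non-GC non-N); the ungapped length excludes every N base.  Percentages
    are rounded half-up to the precision they are conventionally printed
    at (GC 2 decimals, ungapped share 1 decimal).
    """
    if not seqs.records:
        raise ValueError("cannot summarize an empty sequence set")
    lengths = seqs.lengths
    total = seqs.total_length
    curve = dict(nx_curve(lengths))
    non_n = total - seqs.n_bases
    gc_percent = round_half_up(100.0 * seqs.gc_bases / non_n, 2) if non_n else 0.0
    ungapped = non_n
    arr = np.asarray(lengths, dtype=np.int64)
    frac_ge = {
        int(t): float(arr[arr >= t].sum()) / total for t in thresholds
    }
    return ContiguityStats(
        total_bp=total,
        count=len(lengths),
        max_bp=int(arr.max()),
        mean_bp=total / len(lengths),
        n50=curve[50],
        l50=l50(lengths),
        nx=curve,
        gc_percent=gc_percent,
        ungapped_bp=ungapped,
        ungapped_percent=ungapped_percent(ungapped, total),
        frac_ge_thresholds=frac_ge,
        is_scaffold_level=seqs.is_scaffold_level,
    )
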