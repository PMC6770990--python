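"""Synthetic diploid genomes and shotgun read simulation.

This module provides the ground truth against which every downstream stage
of the pipeline is validated: a diploid genome with a known repeat content,
SNP heterozygosity and GC composition, a paired-end short-read simulator
with uniform substitution errors, and a small annotated gene set with
deliberate gene-model defects for exercising the annotation filter.

The genome model is intentionally simple.  Repeats are built as mutated
copies of a handful of random family seed units, interleaved with unique
background sequence, so that shared repeat k-mers pile up into the
high-depth tail of the k-mer spectrum while the unique portion forms the
homozygous peak.  Heterozygosity is injected as independent single-base
substitutions between the two haplotypes; indels and structural variation
are deliberately out of scope because the downstream k-mer heterozygosity
model assumes substitution-style variation.

Every operation takes an explicit integer seed and draws from one
``numpy.random.default_rng`` generator in a documented, fixed order, so the
same configuration always yields byte-identical FASTA/FASTQ output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, GenoprofError
from .util import decode_codes

__all__ = [
    "SimulationConfig",
    "DiploidGenome",
    "ReadSimConfig",
    "ReadSet",
    "synthesize_diploid",
    "simulate_reads",
    "synthesize_gene_set",
    "write_fasta",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic diploid genome.

    Defaults describe the kind of teleost genome the pipeline targets:
    ~45% repetitive sequence, 0.14% SNP heterozygosity (14 SNPs per 10 kb)
    and ~41% GC.  ``repeat_copy_divergence`` is the per-base substitution
    rate applied independently to every repeat copy relative to its family
    seed unit; the low default (0.5%) emulates young, homogeneous repeat
    families whose copies still share most of their k-mers.
    """

    haploid_length: int
    repeat_fraction: float = 0.45
    n_repeat_families: int = 20
    repeat_unit_length: int = 500
    repeat_copy_divergence: float = 0.005
    het_rate: float = 0.0014
    gc_target: float = 0.41
    seed: int = 0

    def validate(self) -> None:
        if self.haploid_length < 10 * self.repeat_unit_length:
            raise ConfigurationError(
                "haploid_length must be at least 10 * repeat_unit_length "
                f"(got haploid_length={self.haploid_length}, "
                f"repeat_unit_length={self.repeat_unit_length})"
            )
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ConfigurationError(
                f"repeat_fraction must be in [0, 1], got {self.repeat_fraction}"
            )
        if self.n_repeat_families < 1:
            raise ConfigurationError(
                f"n_repeat_families must be >= 1, got {self.n_repeat_families}"
            )
        if self.repeat_unit_length < 1:
            raise ConfigurationError(
                f"repeat_unit_length must be >= 1, got {self.repeat_unit_length}"
            )
        if not 0.0 <= self.repeat_copy_divergence <= 0.05:
            raise ConfigurationError(
                "repeat_copy_divergence must be in [0, 0.05], "
                f"got {self.repeat_copy_divergence}"
            )
        if not 0.0 <= self.het_rate <= 0.05:
            raise ConfigurationError(
                f"het_rate must be in [0, 0.05], got {self.het_rate}"
            )
        if not 0.0 < self.gc_target < 1.0:
            raise ConfigurationError(
                f"gc_target must be in (0, 1), got {self.gc_target}"
            )


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the paired-end shotgun read simulator.

    Defaults mirror a standard Illumina short-insert library: 150 bp reads
    from ~470 bp inserts.  ``error_rate`` is the per-base substitution
    probability; quality-trimmed real data typically sits in the 0.1-1%
    range, and the default of 0.2% is a parameter, not an assertion about
    any particular instrument.
    """

    read_length: int = 150
    coverage: float = 60.0
    error_rate: float = 0.002
    insert_mean: int = 470
    insert_sd: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.read_length < 1:
            raise ConfigurationError(
                f"read_length must be >= 1, got {self.read_length}"
            )
        if self.coverage <= 0:
            raise ConfigurationError(
                f"coverage must be > 0, got {self.coverage}"
            )
        if not 0.0 <= self.error_rate < 0.2:
            raise ConfigurationError(
                f"error_rate must be in [0, 0.2), got {self.error_rate}"
            )
        if self.insert_mean < 2 * self.read_length:
            raise ConfigurationError(
                "insert_mean must be >= 2 * read_length "
                f"(got insert_mean={self.insert_mean}, "
                f"read_length={self.read_length})"
            )
        if self.insert_sd < 0:
            raise ConfigurationError(
                f"insert_sd must be >= 0, got {self.insert_sd}"
            )


# ---------------------------------------------------------------------------
# diploid genome
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DiploidGenome:
    """A pair of equal-length haplotypes plus the ground truth that created
    them: repeat intervals (0-based half-open, on haplotype A) and the SNP
    positions at which the haplotypes differ."""

    a_codes: np.ndarray
    b_codes: np.ndarray
    repeat_intervals: list[tuple[int, int]]
    snp_positions: np.ndarray

    def __len__(self) -> int:
        return int(self.a_codes.size)

    @cached_property
    def haplotype_a(self) -> str:
        return decode_codes(self.a_codes)

    @cached_property
    def haplotype_b(self) -> str:
        return decode_codes(self.b_codes)

    @property
    def repeat_bp(self) -> int:
        return sum(e - s for s, e in self.repeat_intervals)

    def write_fasta(self, path) -> None:
        write_fasta(
            [("haplotype_A", self.haplotype_a), ("haplotype_B", self.haplotype_b)],
            path,
        )

    def write_truth_tables(self, prefix) -> None:
        """Write SNP positions (TSV: pos, allele_a, allele_b) and repeat
        intervals (BED: name, start, end; 0-based half-open)."""
        prefix = Path(prefix)
        with open(f"{prefix}.snps.tsv", "w") as fh:
            fh.write("position\tallele_a\tallele_b\n")
            for pos in self.snp_positions:
                fh.write(
                    f"{int(pos)}\t{self.haplotype_a[pos]}\t{self.haplotype_b[pos]}\n"
                )
        with open(f"{prefix}.repeats.bed", "w") as fh:
            for s, e in self.repeat_intervals:
                fh.write(f"haplotype_A\t{s}\t{e}\n")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def synthesize_diploid(config: SimulationConfig) -> DiploidGenome:
    """Generate a diploid genome according to ``config``.

    RNG stream order (fixed; new features must append, never reorder):
      1. repeat family seed units
      2. per-copy family assignment
      3. per-copy divergence mutation mask, then replacement base shifts
      4. inter-repeat gap lengths (multinomial split of the unique bp)
      5. unique background bases
      6. SNP position mask, then SNP allele shifts

    Repeat placement draws the gaps between copies from a multinomial, so
    the realized repeat fraction equals the requested one up to the
    granularity of a single repeat unit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.haploid_length
    unit = config.repeat_unit_length
    probs = _base_probs(config.gc_target)

    n_copies = 0
    if config.repeat_fraction > 0:
        n_copies = int(round(config.repeat_fraction * L / unit))

    copies = np.empty((0, unit), dtype=np.uint8)
    if n_copies:
        families = rng.choice(4, size=(config.n_repeat_families, unit), p=probs)
        families = families.astype(np.uint8)
        fam_idx = rng.integers(0, config.n_repeat_families, size=n_copies)
        copies = families[fam_idx].copy()
        if config.repeat_copy_divergence > 0:
            mask = rng.random(copies.shape) < config.repeat_copy_divergence
            shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            copies[mask] = (copies[mask] + shifts) % 4

    free = L - n_copies * unit
    gaps = rng.multinomial(free, [1.0 / (n_copies + 1)] * (n_copies + 1))
    background = rng.choice(4, size=free, p=probs).astype(np.uint8)

    a = np.empty(L, dtype=np.uint8)
    repeat_intervals: list[tuple[int, int]] = []
    pos = bg = 0
    for i in range(n_copies):
        g = int(gaps[i])
        a[pos : pos + g] = background[bg : bg + g]
        pos += g
        bg += g
        repeat_intervals.append((pos, pos + unit))
        a[pos : pos + unit] = copies[i]
        pos += unit
    g = int(gaps[n_copies])
    a[pos : pos + g] = background[bg : bg + g]

    snp_positions = np.flatnonzero(rng.random(L) < config.het_rate)
    b = a.copy()
    if snp_positions.size:
        shifts = rng.integers(1, 4, size=snp_positions.size, dtype=np.uint8)
        b[snp_positions] = (a[snp_positions] + shifts) % 4

    return DiploidGenome(a, b, repeat_intervals, snp_positions)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class ReadSet:
    """A simulated paired-end read set.

    Mate sequences are held as 2-bit base codes in two (n_pairs, L) arrays;
    mate 2 is stored already reverse-complemented, i.e. as it would be
    sequenced.  ``total_bases`` is the truth total T used downstream for
    genome-size estimation.
    """

    r1: np.ndarray
    r2: np.ndarray
    read_length: int

    @property
    def n_pairs(self) -> int:
        return int(self.r1.shape[0])

    @property
    def n_reads(self) -> int:
        return 2 * self.n_pairs

    @property
    def total_bases(self) -> int:
        return self.n_reads * self.read_length

    @property
    def mean_read_length(self) -> float:
        return float(self.read_length)

    def sequences(self) -> Iterator[str]:
        """Yield every read as a string: all mate-1 reads, then all mate-2."""
        for mat in (self.r1, self.r2):
            for row in mat:
                yield decode_codes(row)

    def write_fastq(self, path1, path2, name_prefix: str = "pair") -> None:
        """Write the pairs as 4-line Phred+33 FASTQ (constant Q40 symbols);
        downstream k-mer counting ignores qualities."""
        qual = "I" * self.read_length
        for path, mat, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            with open(path, "w") as fh:
                buf: list[str] = []
                for i in range(mat.shape[0]):
                    buf.append(
                        f"@{name_prefix}{i}/{mate}\n{decode_codes(mat[i])}\n+\n{qual}\n"
                    )
                    if len(buf) >= 10000:
                        fh.write("".join(buf))
                        buf.clear()
                fh.write("".join(buf))


def simulate_reads(genome: DiploidGenome, config: ReadSimConfig) -> ReadSet:
    """Simulate paired-end reads from a diploid genome.

    Each pair picks one of the two haplotypes with equal probability, an
    insert length from a normal distribution (clipped to [2L, genome
    length]) and a uniform start position; substitution errors are i.i.d.
    per base at ``error_rate``.  The number of pairs is
    ``round(coverage * |genome| / (2L))`` so the realized coverage matches
    the request to within one read pair.

    RNG stream order: haplotype choices, insert lengths, start positions,
    error mask, error base shifts.
    """
    config.validate()
    G = len(genome)
    L = config.read_length
    if G == 0:
        raise GenoprofError("cannot simulate reads from an empty genome")
    if config.insert_mean > G:
        raise GenoprofError(
            f"insert_mean ({config.insert_mean}) longer than genome ({G})"
        )
    if 2 * L > G:
        raise GenoprofError(f"read pair (2x{L} bp) longer than genome ({G})")

    rng = np.random.default_rng(config.seed)
    n_pairs = int(round(config.coverage * G / (2 * L)))

    hap = rng.integers(0, 2, size=n_pairs)
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs))
    inserts = np.clip(inserts.astype(np.int64), 2 * L, G)
    starts = np.floor(rng.random(n_pairs) * (G - inserts + 1)).astype(np.int64)

    haps = np.stack([genome.a_codes, genome.b_codes])
    offs = np.arange(L, dtype=np.int64)
    r1 = haps[hap[:, None], starts[:, None] + offs]
    r2_fwd = haps[hap[:, None], (starts + inserts - L)[:, None] + offs]
    r2 = (np.uint8(3) - r2_fwd)[:, ::-1]  # reverse complement

    if config.error_rate > 0:
        both = np.concatenate([r1, r2], axis=1)
        mask = rng.random(both.shape) < config.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        both[mask] = (both[mask] + shifts) % 4
        r1, r2 = both[:, :L], both[:, L:]

    return ReadSet(np.ascontiguousarray(r1), np.ascontiguousarray(r2), L)


# ---------------------------------------------------------------------------
# FASTA writing
# ---------------------------------------------------------------------------

def write_fasta(records, path, width: int = 80) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# toy annotated gene set
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.41) -> str:
    codes = rng.choice(4, size=n, p=_base_probs(gc)).astype(np.uint8)
    return decode_codes(codes)


def synthesize_gene_set(seed: int = 0, n_valid: int = 12):
    """Build a single synthetic contig carrying an annotated gene set with
    known defects, as a test-bed for the gene-model filter.

    Returns ``(genome_seq, models, truth)`` where ``truth`` maps each
    transcript id to its expected filter outcome: ``retained``, ``short``,
    ``bad_frame``, ``no_start``, ``no_stop`` or ``internal_stop``.  The set
    contains ``n_valid`` clean genes plus two short-CDS, one frame-shifted,
    two start-less, two stop-less and one internal-stop gene (20 genes at
    the default), mixing strands and single/two-exon structures.
    """
    from .annotation import GeneModel  # deferred: annotation does not import us

    rng = np.random.default_rng(seed)
    categories = (
        ["retained"] * n_valid
        + ["short"] * 2
        + ["bad_frame"]
        + ["no_start"] * 2
        + ["no_stop"] * 2
        + ["internal_stop"]
    )

    parts: list[str] = []
    models: list[GeneModel] = []
    truth: dict[str, str] = {}
    cursor = 0

    def emit_spacer() -> None:
        nonlocal cursor
        spacer = _random_dna(rng, int(rng.integers(200, 400)))
        parts.append(spacer)
        cursor += len(spacer)

    emit_spacer()
    for i, cat in enumerate(categories):
        n_codons = int(rng.integers(50, 100))
        body = _random_sense_codons(rng, n_codons)
        if cat == "retained":
            cds = "ATG" + body + "TAA"
        elif cat == "short":
            cds = "ATG" + _random_sense_codons(rng, 47) + "TAA"  # 147 nt
        elif cat == "bad_frame":
            cds = "ATG" + body + "TAA" + "A"  # length % 3 == 1
        elif cat == "no_start":
            cds = "CTG" + body + "TAA"
        elif cat == "no_stop":
            cds = "ATG" + body + "AAA"
        elif cat == "internal_stop":
            half = (n_codons // 2) * 3
            cds = "ATG" + body[:half] + "TGA" + body[half:] + "TAA"
        else:  # pragma: no cover
            raise AssertionError(cat)

        strand = "+" if i % 2 == 0 else "-"
        spliced = i % 3 == 0 and len(cds) > 60
        gid, tid = f"gene{i:02d}", f"mRNA{i:02d}"
        truth[tid] = cat

        placed = cds if strand == "+" else _revcomp_str(cds)
        if spliced:
            cut = (len(cds) // 2) // 3 * 3 + 1  # deliberately off codon boundary
            intron = _random_dna(rng, 60)
            if strand == "+":
                seg_a, seg_b = cds[:cut], cds[cut:]
                genomic = seg_a + intron + seg_b
                s1 = cursor + 1
                e1 = s1 + len(seg_a) - 1
                s2 = e1 + len(intron) + 1
                e2 = s2 + len(seg_b) - 1
                phase2 = (3 - len(seg_a) % 3) % 3
                segs = [(s1, e1, 0), (s2, e2, phase2)]
            else:
                # transcription-first piece sits at the genomic end
                seg_a, seg_b = cds[:cut], cds[cut:]
                genomic = _revcomp_str(seg_b) + intron + _revcomp_str(seg_a)
                s1 = cursor + 1
                e1 = s1 + len(seg_b) - 1
                s2 = e1 + len(intron) + 1
                e2 = s2 + len(seg_a) - 1
                phase1 = (3 - len(seg_a) % 3) % 3
                segs = [(s1, e1, phase1), (s2, e2, 0)]
            parts.append(genomic)
            cursor += len(genomic)
        else:
            s1 = cursor + 1
            e1 = s1 + len(placed) - 1
            segs = [(s1, e1, 0)]
            parts.append(placed)
            cursor += len(placed)

        exons = [(s, e) for s, e, _ in segs]
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=tid,
                sequence_id="toy_contig",
                strand=strand,
                exons=exons,
                cds_segments=segs,
            )
        )
        emit_spacer()

    return "".join(parts), models, truth


def _revcomp_str(seq: str) -> str:
    from .util import revcomp

    return revcomp(seq)
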