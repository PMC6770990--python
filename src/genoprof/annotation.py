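"""Gene-model validation, filtering and annotation summaries.

Implements the standard post-prediction QC of a draft-genome gene set:
extraction of spliced coding sequences from GFF3 gene models (strand and
phase aware), a structural filter that removes models lacking a start or
stop codon, containing an in-frame stop, out of frame, or with a CDS
shorter than a minimum length, plus whole-annotation summary statistics
and completeness (BUSCO-style category) percentage tables.

Coordinates are GFF3 1-based inclusive at the API surface.  The terminal
stop codon is considered part of the CDS, so "ends with a stop" tests the
final codon of the extracted sequence.  Only the standard genetic code is
supported.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .errors import GenoprofError
from .util import revcomp, round_half_up

__all__ = [
    "GeneModel",
    "FilterReport",
    "AnnotationSummary",
    "CompletenessSummary",
    "ParsedAnnotation",
    "parse_gff3",
    "write_gff3",
    "extract_spliced_cds",
    "filter_gene_models",
    "surviving_genes",
    "summarize_annotation",
    "completeness_percentages",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
DEFAULT_MIN_CDS_LENGTH = 150

# filter rules in their fixed evaluation order; a removed model is
# attributed to the first rule it fails
FILTER_RULES = ("short", "bad_frame", "no_start", "no_stop", "internal_stop")


@dataclass
class GeneModel:
    """One spliced coding gene model (a single transcript).

    ``exons`` and ``cds_segments`` are 1-based inclusive intervals sorted
    by start and non-overlapping; CDS segments carry their GFF3 phase (the
    number of bases to trim from the segment's transcription start to
    reach a codon boundary).
    """

    gene_id: str
    transcript_id: str
    sequence_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exons or [(s, e) for s, e, _ in self.cds_segments]
        return min(s for s, _ in ivs), max(e for _, e in ivs)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GenoprofError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        for name, ivs in (("exons", self.exons), ("cds_segments", self.cds_segments)):
            prev_end = 0
            for iv in ivs:
                s, e = iv[0], iv[1]
                if s > e or s <= prev_end:
                    raise GenoprofError(
                        f"transcript {self.transcript_id}: {name} must be "
                        "sorted, non-overlapping 1-based intervals"
                    )
                prev_end = e


# ---------------------------------------------------------------------------
# sequence access + CDS extraction
# ---------------------------------------------------------------------------

def _fetch(genome, seq_id: str, start: int, end: int, transcript_id: str) -> str:
    """1-based inclusive fetch from a dict of strings or a pyfaidx.Fasta."""
    try:
        record = genome[seq_id]
    except KeyError:
        raise GenoprofError(
            f"transcript {transcript_id}: sequence {seq_id!r} not in genome"
        ) from None
    if start < 1 or end > len(record):
        raise GenoprofError(
            f"transcript {transcript_id}: coordinates {start}-{end} out of "
            f"bounds for {seq_id!r} (length {len(record)})"
        )
    return str(record[start - 1 : end])


def extract_spliced_cds(model: GeneModel, genome) -> str:
    """Extract the spliced CDS of a gene model from genomic sequence.

    Segments are concatenated in genomic order and reverse-complemented
    for minus-strand models; a non-zero phase on the transcription-first
    segment trims that many leading bases.
    """
    if not model.cds_segments:
        raise GenoprofError(f"transcript {model.transcript_id}: no CDS segments")
    parts = [
        _fetch(genome, model.sequence_id, s, e, model.transcript_id)
        for s, e, _ in model.cds_segments
    ]
    seq = "".join(parts).upper()
    first = model.cds_segments[0] if model.strand == "+" else model.cds_segments[-1]
    if model.strand == "-":
        seq = revcomp(seq)
    phase = first[2]
    if phase:
        seq = seq[phase:]
    return seq


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Bookkeeping of the gene-model filter; counts are conserved:
    n_input == n_retained + all removals.  ``n_unparseable`` counts models
    that could not be read from the input at all and is tracked outside
    the conservation sum."""

    n_input: int = 0
    n_removed_short_cds: int = 0
    n_removed_bad_frame: int = 0
    n_removed_no_start: int = 0
    n_removed_no_stop: int = 0
    n_removed_internal_stop: int = 0
    n_retained: int = 0
    n_unparseable: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_short_cds
            + self.n_removed_bad_frame
            + self.n_removed_no_start
            + self.n_removed_no_stop
            + self.n_removed_internal_stop
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__, n_removed=self.n_removed)


def classify_cds(seq: str, min_cds_length: int = DEFAULT_MIN_CDS_LENGTH) -> str:
    """First failing structural rule of a spliced CDS, or ``"retained"``.

    Rules, in fixed order: length >= ``min_cds_length``; length divisible
    by 3; starts with ATG; ends with a stop codon; no in-frame stop before
    the final codon.
    """
    seq = seq.upper()
    if len(seq) < min_cds_length:
        return "short"
    if len(seq) % 3 != 0:
        return "bad_frame"
    if not seq.startswith(START_CODON):
        return "no_start"
    if seq[-3:] not in STOP_CODONS:
        return "no_stop"
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    return "retained"


_RULE_FIELD = {
    "short": "n_removed_short_cds",
    "bad_frame": "n_removed_bad_frame",
    "no_start": "n_removed_no_start",
    "no_stop": "n_removed_no_stop",
    "internal_stop": "n_removed_internal_stop",
}


def filter_gene_models(
    models: Iterable[GeneModel],
    genome,
    min_cds_length: int = DEFAULT_MIN_CDS_LENGTH,
) -> tuple[list[GeneModel], FilterReport]:
    """Apply the structural CDS filter to every transcript model.

    Returns the retained models and a :class:`FilterReport` attributing
    each removal to the first rule it failed.  Filtering is per
    transcript; use :func:`surviving_genes` for the gene-level view (a
    gene survives if at least one of its transcripts does).
    """
    report = FilterReport()
    retained: list[GeneModel] = []
    for model in models:
        report.n_input += 1
        verdict = classify_cds(
            extract_spliced_cds(model, genome), min_cds_length
        )
        if verdict == "retained":
            retained.append(model)
            report.n_retained += 1
        else:
            setattr(report, _RULE_FIELD[verdict], getattr(report, _RULE_FIELD[verdict]) + 1)
    return retained, report


def surviving_genes(retained: Iterable[GeneModel]) -> set[str]:
    return {m.gene_id for m in retained}


# ---------------------------------------------------------------------------
# annotation summary
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSummary:
    n_genes: int
    n_transcripts: int
    mean_gene_length: float
    mean_cds_length: float
    mean_exon_length: float
    mean_intron_length: float
    mean_exons_per_cds: float
    pct_genome_in_genes: float
    pct_genome_in_cds: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _union_length(intervals_by_seq: Mapping[str, list[tuple[int, int]]]) -> int:
    total = 0
    for ivs in intervals_by_seq.values():
        ivs = sorted(ivs)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e + 1:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s + 1
    return total


def summarize_annotation(
    models: Iterable[GeneModel], genome_length: int
) -> AnnotationSummary:
    """Whole-annotation summary statistics.

    Gene length is the gene span (first exon start to last exon end);
    means are arithmetic means over transcripts (exon/intron means over
    all exons/introns).  Genome-coverage percentages are computed on the
    merged interval union across all genes so overlapping models are not
    double-counted, and are rounded half-up to 1 decimal.
    """
    models = list(models)
    if not models:
        raise ValueError("cannot summarize an empty gene set")
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")

    gene_lengths: list[int] = []
    cds_lengths: list[int] = []
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    exons_per_cds: list[int] = []
    gene_spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds_ivs: dict[str, list[tuple[int, int]]] = defaultdict(list)
    gene_ids = set()

    for m in models:
        gene_ids.add(m.gene_id)
        s, e = m.span
        gene_lengths.append(e - s + 1)
        gene_spans[m.sequence_id].append((s, e))
        cds_lengths.append(m.spliced_cds_length)
        exons_per_cds.append(len(m.cds_segments))
        for cs, ce, _ in m.cds_segments:
            cds_ivs[m.sequence_id].append((cs, ce))
        exons = m.exons or [(a, b) for a, b, _ in m.cds_segments]
        for es, ee in exons:
            exon_lengths.append(ee - es + 1)
        for (_, prev_e), (nxt_s, _unused) in zip(exons, exons[1:]):
            intron_lengths.append(nxt_s - prev_e - 1)

    def _mean(xs):
        return sum(xs) / len(xs) if xs else 0.0

    return AnnotationSummary(
        n_genes=len(gene_ids),
        n_transcripts=len(models),
        mean_gene_length=_mean(gene_lengths),
        mean_cds_length=_mean(cds_lengths),
        mean_exon_length=_mean(exon_lengths),
        mean_intron_length=_mean(intron_lengths),
        mean_exons_per_cds=_mean(exons_per_cds),
        pct_genome_in_genes=round_half_up(
            100.0 * _union_length(gene_spans) / genome_length, 1
        ),
        pct_genome_in_cds=round_half_up(
            100.0 * _union_length(cds_ivs) / genome_length, 1
        ),
    )


# ---------------------------------------------------------------------------
# completeness (BUSCO-style category) percentages
# ---------------------------------------------------------------------------

@dataclass
class CompletenessSummary:
    """Per-category counts and percentages of a core-gene completeness
    screen.  ``reconciles`` is False when the category counts do not sum
    to the stated total (some published tables nest duplicated genes
    inside the complete count, which this computation does not guess at)."""

    total_core_genes: int
    counts: dict[str, int]
    percentages: dict[str, float]
    counts_sum: int
    reconciles: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def completeness_percentages(
    counts: Mapping[str, int], total: int
) -> CompletenessSummary:
    """Percentage of ``total`` per category, half-up rounded to 2 decimals."""
    if total <= 0:
        raise ValueError(f"total must be > 0, got {total}")
    for cat, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for category {cat!r}: {n}")
    pct = {cat: round_half_up(100.0 * n / total, 2) for cat, n in counts.items()}
    csum = sum(counts.values())
    return CompletenessSummary(
        total_core_genes=total,
        counts=dict(counts),
        percentages=pct,
        counts_sum=csum,
        reconciles=(csum == total),
    )


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

class ParsedAnnotation(NamedTuple):
    models: list[GeneModel]
    n_unparseable: int


def parse_gff3(path) -> ParsedAnnotation:
    """Read gene models (gene/mRNA/exon/CDS features, phase honored) from
    a GFF3 file.  Transcripts that cannot be assembled into a valid model
    are skipped and counted in ``n_unparseable``."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    n_bad = 0
    for mrna in db.features_of_type(("mRNA", "transcript")):
        try:
            parents = mrna.attributes.get("Parent", [])
            gene_id = parents[0] if parents else mrna.id
            exons = [
                (f.start, f.end)
                for f in db.children(mrna.id, featuretype="exon", order_by="start")
            ]
            cds = [
                (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(mrna.id, featuretype="CDS", order_by="start")
            ]
            if not cds:
                n_bad += 1
                continue
            model = GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                sequence_id=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
            )
            model.validate()
            models.append(model)
        except (GenoprofError, ValueError):
            n_bad += 1
    return ParsedAnnotation(models, n_bad)


def write_gff3(models: Iterable[GeneModel], path, source: str = "genoprof") -> None:
    """Write gene models as GFF3 (one gene + mRNA per transcript, with
    exon and CDS children)."""
    by_gene: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_gene[m.gene_id].append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, ms in by_gene.items():
            g_s = min(m.span[0] for m in ms)
            g_e = max(m.span[1] for m in ms)
            first = ms[0]
            fh.write(
                f"{first.sequence_id}\t{source}\tgene\t{g_s}\t{g_e}\t.\t"
                f"{first.strand}\t.\tID={gene_id}\n"
            )
            for m in ms:
                s, e = m.span
                fh.write(
                    f"{m.sequence_id}\t{source}\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for i, (es, ee) in enumerate(m.exons):
                    fh.write(
                        f"{m.sequence_id}\t{source}\texon\t{es}\t{ee}\t.\t"
                        f"{m.strand}\t.\tID={m.transcript_id}.exon{i};"
                        f"Parent={m.transcript_id}\n"
                    )
                for i, (cs, ce, phase) in enumerate(m.cds_segments):
                    fh.write(
                        f"{m.sequence_id}\t{source}\tCDS\t{cs}\t{ce}\t.\t"
                        f"{m.strand}\t{phase}\tID={m.transcript_id}.cds{i};"
                        f"Parent={m.transcript_id}\n"
                    )
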