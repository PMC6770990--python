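"""Cross-assembly comparison and pipeline orchestration.

Holds the Percidae comparison table used by the ``compare`` operation (a
bundled three-species fixture; user TSVs with the same columns are
accepted), the Pearson correlation helper behind repeat-content vs
genome-size comparisons, and ``run_pipeline``, which chains the simulate /
count / profile / assembly-stats / gene-filter / completeness / compare
stages into one JSON report bundle.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _version
from .annotation import completeness_percentages, filter_gene_models, parse_gff3, write_gff3
from .assembly import sequence_set_from_fasta, split_scaffolds, summarize
from .errors import GenoprofError
from .kmers import count_canonical_kmers, write_histogram
from .profile import profile as profile_histogram
from .simulate import ReadSimConfig, SimulationConfig, simulate_reads, synthesize_diploid

logger = logging.getLogger("genoprof")

__all__ = [
    "AssemblyComparisonRow",
    "PERCIDAE_ASSEMBLIES",
    "pearson_correlation",
    "load_comparison_table",
    "run_pipeline",
    "validate_bundle",
]


@dataclass(frozen=True)
class AssemblyComparisonRow:
    """One species in a cross-assembly comparison table."""

    species_label: str
    repeat_content_pct: float
    genome_size_mb: float
    contigs_n50_mb: float
    n_contigs: int
    n_coding_genes: int
    ungapped_mb: Optional[float] = None


# Published Percidae draft assemblies (total/ungapped lengths in Mb).
PERCIDAE_ASSEMBLIES: tuple[AssemblyComparisonRow, ...] = (
    AssemblyComparisonRow("Yellow perch", 41.0, 877.4, 4.2, 1097, 23749, 877.0),
    AssemblyComparisonRow("Pikeperch", 39.0, 900.5, 3.0, 1966, 21249, 899.8),
    AssemblyComparisonRow("Eurasian perch", 33.0, 958.2, 0.0182, 100821, 23397, 851.6),
)


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson R with a two-sided p-value from the t-distribution
    with n - 2 degrees of freedom."""
    from scipy import stats

    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have equal length")
    if xs.size < 3:
        raise ValueError(f"need at least 3 points, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise GenoprofError("correlation undefined for a constant vector")
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def load_comparison_table(path) -> list[AssemblyComparisonRow]:
    """Read a comparison table from TSV with the AssemblyComparisonRow
    column names."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {
        "species_label",
        "repeat_content_pct",
        "genome_size_mb",
        "contigs_n50_mb",
        "n_contigs",
        "n_coding_genes",
    }
    missing = required - set(df.columns)
    if missing:
        raise GenoprofError(f"comparison table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.to_dict(orient="records"):
        rows.append(
            AssemblyComparisonRow(
                species_label=str(rec["species_label"]),
                repeat_content_pct=float(rec["repeat_content_pct"]),
                genome_size_mb=float(rec["genome_size_mb"]),
                contigs_n50_mb=float(rec["contigs_n50_mb"]),
                n_contigs=int(rec["n_contigs"]),
                n_coding_genes=int(rec["n_coding_genes"]),
                ungapped_mb=float(rec["ungapped_mb"]) if "ungapped_mb" in rec else None,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_STAGES = (
    "simulate",
    "count",
    "profile",
    "asm_stats",
    "gene_filter",
    "completeness",
    "compare",
)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the requested stages and write one JSON bundle plus
    per-stage artifacts under ``outdir``.

    ``config`` maps stage names to their parameter dicts; consecutive
    simulate -> count -> profile stages hand their products to each other
    in memory.  Raises :class:`GenoprofError` on an empty or unknown
    stage configuration (usage errors) and on missing stage inputs.
    """
    stages = [s for s in config if s in _STAGES]
    unknown = [s for s in config if s not in _STAGES]
    if unknown:
        raise GenoprofError(f"unknown pipeline stage(s): {unknown}")
    if not stages:
        raise GenoprofError(
            f"empty pipeline configuration; configure at least one of {_STAGES}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "genoprof_version": _version,
        "parameters": config,
        "stages": {},
    }

    reads = None
    hist = None

    if "simulate" in config:
        params = dict(config["simulate"])
        read_keys = {f.name for f in ReadSimConfig.__dataclass_fields__.values()} - {"seed"}
        sim_params = {k: v for k, v in params.items() if k not in read_keys}
        read_params = {k: v for k, v in params.items() if k in read_keys}
        sim_cfg = SimulationConfig(**sim_params)
        read_cfg = ReadSimConfig(seed=sim_cfg.seed + 1, **read_params)
        logger.info("simulate: %s", sim_cfg)
        genome = synthesize_diploid(sim_cfg)
        reads = simulate_reads(genome, read_cfg)
        genome.write_fasta(outdir / "genome.fa")
        genome.write_truth_tables(outdir / "truth")
        reads.write_fastq(outdir / "reads_1.fastq", outdir / "reads_2.fastq")
        bundle["stages"]["simulate"] = {
            "haploid_length": len(genome),
            "repeat_bp": genome.repeat_bp,
            "n_snps": int(genome.snp_positions.size),
            "n_read_pairs": reads.n_pairs,
            "total_bases": reads.total_bases,
        }

    if "count" in config:
        params = dict(config.get("count") or {})
        k = int(params.get("k", 19))
        if reads is None:
            raise GenoprofError("count stage needs a simulate stage (or use the CLI on FASTQ files)")
        logger.info("count: k=%d over %d reads", k, reads.n_reads)
        hist = count_canonical_kmers(reads, k)
        write_histogram(hist, outdir / f"kmer_hist_k{k}.tsv")
        bundle["stages"]["count"] = {
            "k": k,
            "distinct_kmers": hist.n_distinct,
            "total_kmers": hist.total_kmers,
        }

    if "profile" in config:
        params = dict(config.get("profile") or {})
        if hist is None:
            raise GenoprofError("profile stage needs a count stage")
        prof = profile_histogram(
            hist,
            sc_lo=float(params.get("sc_lo", 0.5)),
            sc_hi=float(params.get("sc_hi", 1.5)),
        )
        bundle["stages"]["profile"] = prof.to_dict()
        with open(outdir / "profile.json", "w") as fh:
            json.dump(prof.to_dict(), fh, indent=2)

    if "asm_stats" in config:
        params = dict(config["asm_stats"])
        if "fasta" not in params:
            raise GenoprofError("asm_stats stage needs 'fasta'")
        seqs = sequence_set_from_fasta(params["fasta"])
        stats = summarize(seqs)
        result = {"scaffolds": stats.to_dict()}
        if params.get("split_gaps"):
            contigs = split_scaffolds(seqs, int(params["split_gaps"]))
            if contigs.records:
                result["contigs"] = summarize(contigs).to_dict()
        bundle["stages"]["asm_stats"] = result

    if "gene_filter" in config:
        params = dict(config["gene_filter"])
        if "gff3" not in params or "fasta" not in params:
            raise GenoprofError("gene_filter stage needs 'gff3' and 'fasta'")
        import pyfaidx

        parsed = parse_gff3(params["gff3"])
        genome_fa = pyfaidx.Fasta(params["fasta"])
        retained, rep = filter_gene_models(
            parsed.models, genome_fa, int(params.get("min_cds", 150))
        )
        rep.n_unparseable = parsed.n_unparseable
        write_gff3(retained, outdir / "retained.gff3")
        bundle["stages"]["gene_filter"] = rep.to_dict()

    if "completeness" in config:
        params = dict(config["completeness"])
        if "counts" not in params or "total" not in params:
            raise GenoprofError("completeness stage needs 'counts' and 'total'")
        summary = completeness_percentages(params["counts"], int(params["total"]))
        bundle["stages"]["completeness"] = summary.to_dict()

    if "compare" in config:
        params = dict(config.get("compare") or {})
        rows = (
            load_comparison_table(params["table"])
            if "table" in params
            else list(PERCIDAE_ASSEMBLIES)
        )
        x_field = params.get("x", "repeat_content_pct")
        y_field = params.get("y", "genome_size_mb")
        xs = [getattr(r, x_field) for r in rows]
        ys = [getattr(r, y_field) for r in rows]
        r, p = pearson_correlation(xs, ys)
        bundle["stages"]["compare"] = {
            "x": x_field,
            "y": y_field,
            "n_species": len(rows),
            "species": [row.species_label for row in rows],
            "pearson_r": r,
            "p_value": p,
        }

    validate_bundle(bundle)
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle


def validate_bundle(bundle: dict) -> None:
    """Check the report bundle's structure and JSON-serializability."""
    for key in ("genoprof_version", "parameters", "stages"):
        if key not in bundle:
            raise GenoprofError(f"invalid bundle: missing {key!r}")
    if not isinstance(bundle["stages"], dict):
        raise GenoprofError("invalid bundle: 'stages' must be a mapping")
    for name in bundle["stages"]:
        if name not in _STAGES:
            raise GenoprofError(f"invalid bundle: unknown stage {name!r}")
    try:
        json.dumps(bundle)
    except (TypeError, ValueError) as exc:
        raise GenoprofError(f"bundle is not JSON-serializable: {exc}") from exc
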