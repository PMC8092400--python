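"""Per-sample RPM/TPM, the log2 proximal:distal poly(A) ratio and
poly(A)-read-based isoform abundance estimates.

Definitions used throughout:

* RPM — reads per million primary mapped reads in the sample. The
  denominator is the whole library, not only poly(A) reads, so proximal and
  distal RPM stay comparable across samples with different tail-capture
  efficiency.
* TPM — per-gene counts (all primary mapped reads overlapping the gene's
  exonic union, strand-aware) divided by the gene's effective length (the
  exonic length of its longest, i.e. distal, isoform), renormalized to sum
  to 10^6 over genes.
* log2 poly(A) ratio — log2[(proximal RPM + eps) / (distal RPM + eps)],
  eps being a pseudocount of one read converted to RPM units (configurable,
  0 allowed when both sides are positive).
* Isoform abundance — the poly(A)-read mixing fraction
  f = proximal/(proximal+distal) splits the gene TPM into proximal and
  distal isoform TPM. Each transcript contributes exactly one 3' end, so f
  estimates the molar fraction directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .clusters import PolyACluster, cluster_id
from .gffio import GeneModel

log = logging.getLogger(__name__)


def rpm(count: float, total_mapped: float) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0 for RPM")
    return count / total_mapped * 1e6


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from counts and effective lengths.

    All-zero counts yield all-zero TPM (logged) rather than an error.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be > 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        log.warning("all gene counts are zero; TPM set to zero")
        return np.zeros_like(rate)
    return rate / total * 1e6


def polya_ratio(proximal_rpm: float, distal_rpm: float, pseudocount: float = 0.0) -> float:
    """log2[(proximal RPM + eps)/(distal RPM + eps)]."""
    if proximal_rpm < 0 or distal_rpm < 0:
        raise ValueError("RPM inputs must be >= 0")
    return math.log2((proximal_rpm + pseudocount) / (distal_rpm + pseudocount))


def isoform_abundance(
    gene_tpm: float, proximal_pa_reads: float, distal_pa_reads: float
) -> tuple[float, float]:
    """Split a gene's TPM into (proximal, distal) isoform TPM using the
    poly(A)-read mixing fraction. Undefined (NaN, NaN) with zero poly(A)
    reads."""
    total = proximal_pa_reads + distal_pa_reads
    if total <= 0:
        log.warning("zero poly(A) reads: isoform abundance undefined")
        return math.nan, math.nan
    f = proximal_pa_reads / total
    return gene_tpm * f, gene_tpm * (1 - f)


# --------------------------------------------------------------------------
# per-sample quantification


@dataclass
class SampleQuant:
    """Quantification tables for one sample."""

    sample: str
    total_mapped: int
    gene_table: pd.DataFrame = field(repr=False)  # gene_id, count, length, tpm
    cluster_table: pd.DataFrame = field(repr=False)
    gene_apa: pd.DataFrame = field(repr=False)


def count_gene_reads(
    sam_path, genes: Mapping[str, GeneModel]
) -> tuple[dict[str, int], int]:
    """Count primary mapped reads overlapping each gene's exonic union
    (strand-aware, stranded library). Returns (per-gene counts, total
    primary mapped reads)."""
    unions = {
        gid: (g.chrom, g.strand, g.exonic_union()) for gid, g in genes.items()
    }
    counts = {gid: 0 for gid in genes}
    total = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            strand = "-" if aln.is_reverse else "+"
            blocks = aln.get_blocks()  # 0-based half-open
            for gid, (chrom, gstrand, ivals) in unions.items():
                if chrom != aln.reference_name or gstrand != strand:
                    continue
                if any(b0 < e and b1 > s - 1 for b0, b1 in blocks for s, e in ivals):
                    counts[gid] += 1
    return counts, total


def quantify_sample(
    sample: str,
    sam_path,
    clusters: Sequence[PolyACluster],
    genes: Mapping[str, GeneModel],
    pseudocount_reads: float = 1.0,
) -> SampleQuant:
    """Build the per-sample quant tables from the shared cluster set.

    ``clusters`` is the pooled, classified cluster set; this sample's counts
    are taken from each cluster's per-sample tally.
    """
    gene_counts, total = count_gene_reads(sam_path, genes)
    gids = sorted(genes)
    lengths = [genes[g].effective_length for g in gids]
    counts = [gene_counts[g] for g in gids]
    tpms = tpm(counts, lengths)
    gene_table = pd.DataFrame(
        {"gene_id": gids, "count": counts, "length": lengths, "tpm": tpms}
    )

    rows = []
    for c in clusters:
        n = c.sample_counts.get(sample, 0)
        rows.append(
            {
                "cluster_id": cluster_id(c),
                "gene_id": c.gene_id,
                "class": c.cluster_class,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "summit": c.summit,
                "count": n,
                "rpm": rpm(n, total) if total else 0.0,
            }
        )
    cluster_table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "gene_id", "class", "chrom", "strand",
            "start", "end", "summit", "count", "rpm",
        ],
    )

    eps = rpm(pseudocount_reads, total) if total else 0.0
    apa_rows = []
    for gid in gids:
        sub = cluster_table[cluster_table.gene_id == gid]
        p_reads = int(sub.loc[sub["class"] == "proximal", "count"].sum())
        d_reads = int(sub.loc[sub["class"] == "distal", "count"].sum())
        p_rpm = rpm(p_reads, total) if total else 0.0
        d_rpm = rpm(d_reads, total) if total else 0.0
        gtpm = float(gene_table.loc[gene_table.gene_id == gid, "tpm"].iloc[0])
        p_tpm, d_tpm = isoform_abundance(gtpm, p_reads, d_reads)
        apa_rows.append(
            {
                "gene_id": gid,
                "proximal_reads": p_reads,
                "distal_reads": d_reads,
                "proximal_rpm": p_rpm,
                "distal_rpm": d_rpm,
                "log2_ratio": polya_ratio(p_rpm, d_rpm, eps),
                "proximal_tpm": p_tpm,
                "distal_tpm": d_tpm,
            }
        )
    gene_apa = pd.DataFrame(apa_rows)
    return SampleQuant(sample, total, gene_table, cluster_table, gene_apa)


# --------------------------------------------------------------------------
# stage series

_METRICS = ("tpm", "proximal_rpm", "distal_rpm", "log2_ratio", "proximal_tpm", "distal_tpm")


def stage_series(
    entries: Sequence[tuple[str, int, SampleQuant]],
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy long table over ordered samples.

    ``entries`` are (stage, replicate, SampleQuant). One row per
    (stage, replicate, gene, metric), plus per-stage mean rows with
    replicate = 'mean'. Gene sets are unioned across samples; a sample
    missing a gene contributes NaN (logged).
    """
    if not entries:
        raise ValueError("stage_series needs at least one sample")
    all_genes = sorted({g for _, _, q in entries for g in q.gene_table.gene_id})
    rows = []
    for stage, replicate, q in entries:
        tpm_by_gene = dict(zip(q.gene_table.gene_id, q.gene_table.tpm))
        apa = q.gene_apa.set_index("gene_id")
        if set(tpm_by_gene) != set(all_genes):
            log.warning("sample %s gene set differs; missing values emitted", q.sample)
        for gene in all_genes:
            for metric in _METRICS:
                if metric == "tpm":
                    val = tpm_by_gene.get(gene, math.nan)
                else:
                    val = apa[metric].get(gene, math.nan)
                rows.append(
                    {
                        "stage": stage,
                        "replicate": str(replicate),
                        "sample": q.sample,
                        "gene_id": gene,
                        "metric": metric,
                        "value": float(val),
                    }
                )
    df = pd.DataFrame(rows)
    means = (
        df.groupby(["stage", "gene_id", "metric"], as_index=False)["value"]
        .mean()
        .assign(replicate="mean", sample="")
    )
    out = pd.concat([df, means], ignore_index=True)[
        ["stage", "replicate", "sample", "gene_id", "metric", "value"]
    ]
    if stage_order:
        order = {s: i for i, s in enumerate(stage_order)}
        out = out.sort_values(
            by=["stage", "replicate", "gene_id", "metric"],
            key=lambda col: col.map(order) if col.name == "stage" else col,
            kind="stable",
        ).reset_index(drop=True)
    return out
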