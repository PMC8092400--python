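"""Gene models, GFF3 reading/writing and the coordinate-convention boundary.

Internally every genomic interval is 1-based inclusive with an explicit
strand — the native convention of GFF3 and of SAM POS. BED output is 0-based
half-open; the conversion lives in exactly one pair of functions
(:func:`to_bed`, :func:`from_bed`) so that off-by-one behaviour is auditable
and tested in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gffutils.feature import feature_from_line


# --------------------------------------------------------------------------
# coordinate conversion (the only place 0-based half-open appears)

def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open (BED)."""
    return start - 1, end


def from_bed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (BED) -> 1-based inclusive."""
    return start + 1, end


# --------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform: exon structure plus its 3' end.

    Exons are stored in ascending genomic order as 1-based inclusive
    (start, end) pairs; transcript orientation is derived from the strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        """Exonic (spliced) length in bases."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the annotated 3' terminus."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end

    def exons_in_transcript_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def distal_transcript(self) -> TranscriptModel:
        """The longest annotated isoform; ties go to the most 3' terminus.

        This isoform defines the gene's distal (full-length) 3' end.
        """
        sign = 1 if self.strand == "+" else -1
        return max(self.transcripts, key=lambda t: (t.length, sign * t.three_prime_end))

    @property
    def three_prime_end(self) -> int:
        return self.distal_transcript.three_prime_end

    @property
    def effective_length(self) -> int:
        """Exonic length of the distal isoform (used as the TPM length)."""
        return self.distal_transcript.length

    def exonic_union(self) -> list[tuple[int, int]]:
        """Merged union of exon intervals over all annotated isoforms."""
        ivals = sorted(e for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


# --------------------------------------------------------------------------
# GFF3 I/O


def load_gff3(path) -> dict[str, GeneModel]:
    """Load a gene/mRNA/exon hierarchy from GFF3 into :class:`GeneModel`s.

    Coordinates stay 1-based inclusive. Exon order is normalized to
    ascending genomic coordinates (transcript orientation is recovered from
    the strand). Raises ``ValueError`` naming the offending line for orphan
    exons, strand-less mRNAs and malformed lines.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"line {lineno}: truncated GFF3 line (expected 9 fields)")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed / truncated line
                raise ValueError(f"line {lineno}: malformed GFF3 line ({exc})") from exc
            ftype = feat.featuretype
            if ftype == "gene":
                gid = feat.attributes["ID"][0]
                genes[gid] = {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "start": feat.start,
                    "end": feat.end,
                    "mrnas": [],
                }
            elif ftype == "mRNA":
                if feat.strand not in ("+", "-"):
                    raise ValueError(f"line {lineno}: mRNA with unknown strand {feat.strand!r}")
                tid = feat.attributes["ID"][0]
                parent = feat.attributes["Parent"][0]
                if parent not in genes:
                    raise ValueError(f"line {lineno}: mRNA {tid} references unknown gene {parent}")
                mrnas[tid] = {"gene": parent, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
                genes[parent]["mrnas"].append(tid)
            elif ftype == "exon":
                parents = feat.attributes.get("Parent", [])
                if not parents or parents[0] not in mrnas:
                    raise ValueError(f"line {lineno}: orphan exon (Parent missing or unknown)")
                mrnas[parents[0]]["exons"].append((feat.start, feat.end))
    models: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        gene = GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"])
        for tid in g["mrnas"]:
            m = mrnas[tid]
            gene.transcripts.append(
                TranscriptModel(tid, gid, m["chrom"], m["strand"], tuple(sorted(m["exons"])))
            )
        models[gid] = gene
    return models


def write_gff3(genes: dict[str, GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive, ##gff-version 3 header)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in genes:
            g = genes[gid]
            fh.write(
                f"{g.chrom}\tapakit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tapakit\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gid}\n"
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{g.chrom}\tapakit\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )


def write_bed6(path, rows) -> None:
    """Write BED6 rows given as (chrom, start1, end1, name, score, strand).

    Interval conversion to BED happens here via :func:`to_bed`.
    """
    with open(path, "w") as fh:
        for chrom, start1, end1, name, score, strand in rows:
            b0, b1 = to_bed(start1, end1)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{name}\t{score}\t{strand}\n")
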