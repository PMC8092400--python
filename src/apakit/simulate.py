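"""Synthetic genome, annotation and stranded RNA-seq reads with APA ground truth.

The generator emulates a miniature locus in the style of *Arabidopsis* *FLC*:
a multi-exon gene whose first intron carries three proximal polyadenylation
sites in addition to the distal terminator at the annotated 3' end, plus a
constitutively expressed reference gene on the opposite strand and an
intergenic A-homopolymer used to plant internal-priming artifacts.

Reads are emitted directly as coordinate-sorted SAM alignment records (the
CIGAR is constructed by the generator, so the soft-clip logic of the tail
caller can be exercised without an external aligner), as FASTQ in sequencing
orientation, and as a per-read truth table.

Modelling choices, in brief:

* Reads are sampled per isoform proportionally to molar abundance; fragment
  start positions are uniform along the transcript.
* A fraction ``polya_capture_rate`` of each isoform's reads is its
  3'-terminal fragment: it ends at the isoform's cleavage site (with a small
  normal jitter emulating cleavage microheterogeneity) and carries an
  untemplated poly(A) run encoded as a terminal soft clip, reverse
  complemented for minus-strand transcripts.
* Internal-priming artifacts are reads that present exactly like tail reads
  — templated portion plus a pure-A soft clip — but whose apparent cleavage
  site abuts the planted genomic A-tract, so they are accepted by the tail
  caller and must be removed by the downstream genomic-window filter.
* Around every *declared* cleavage site the genome is built with a "guard
  band" free of transcript-orientation adenosine covering the
  internal-priming window plus the jitter margin, so true sites are never
  confused with genomically templated A-runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .dnautil import revcomp, write_fasta
from .gffio import GeneModel, TranscriptModel, load_gff3, write_gff3

# Tail lengths are truncated at the tail caller's default minimum clip length
# so every emitted tail is in principle callable.
MIN_TAIL_LEN = 4
# Maximum cleavage jitter (bases) and the guard band it implies.
JITTER_MAX = 6
IP_WINDOW = 10  # matches the internal-priming filter's default window
GUARD_DOWN = IP_WINDOW + JITTER_MAX
GUARD_UP = JITTER_MAX

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint of one gene: exons plus proximal/distal cleavage sites."""

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    proximal_pas: tuple[int, ...]
    distal_pas: int

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) inverted")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = e
        terminus = self.end if self.strand == "+" else self.start
        if self.distal_pas != terminus:
            raise ValueError(
                f"{self.gene_id}: distal_pas {self.distal_pas} is not the annotated 3' end {terminus}"
            )
        for p in self.proximal_pas:
            if not (self.start < p < self.end):
                raise ValueError(f"{self.gene_id}: proximal site {p} outside the gene body")
            upstream = p < self.distal_pas if self.strand == "+" else p > self.distal_pas
            if not upstream:
                raise ValueError(f"{self.gene_id}: proximal site {p} not upstream of the distal site")


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint of the miniature chromosome."""

    chrom_name: str = "chr1"
    chrom_length: int = 60_000
    genes: tuple[GeneSpec, ...] = ()
    a_tract: tuple[int, int] = (45_001, 20)  # (start, length)

    def validate(self) -> None:
        for g in self.genes:
            g.validate()
        spans = sorted((g.start, g.end, g.gene_id) for g in self.genes)
        for (s1, e1, id1), (s2, e2, id2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"genes {id1} and {id2} overlap")
        ts, tl = self.a_tract
        for g in self.genes:
            if ts <= g.end and ts + tl - 1 >= g.start:
                raise ValueError(f"a_tract overlaps gene {g.gene_id}")
        max_coord = max([g.end for g in self.genes] + [ts + tl - 1])
        if self.chrom_length < max_coord + GUARD_DOWN:
            raise ValueError("chrom_length smaller than the annotated coordinates")


def default_genome_spec() -> GenomeSpec:
    """The built-in two-gene genome used by the presets.

    ``FLC`` mimics the locus of interest: three exons, three proximal
    cleavage sites inside intron 1 (>= 200 bases apart, so they resolve into
    separate clusters at the default merge distance) and the distal
    terminator at the annotated 3' end. ``RPL`` is a minus-strand two-exon
    reference gene with only the distal site.
    """
    flc = GeneSpec(
        gene_id="FLC",
        strand="+",
        exons=((10_001, 10_400), (13_001, 13_500), (14_001, 15_000)),
        proximal_pas=(10_700, 10_900, 11_100),
        distal_pas=15_000,
    )
    rpl = GeneSpec(
        gene_id="RPL",
        strand="-",
        exons=((30_001, 30_400), (30_801, 31_400)),
        proximal_pas=(),
        distal_pas=30_001,
    )
    return GenomeSpec(genes=(flc, rpl))


@dataclass(frozen=True)
class GeneAbundance:
    """Molar abundances (arbitrary units) of one gene's isoforms."""

    proximal: tuple[float, ...]
    distal: float

    @property
    def total(self) -> float:
        return sum(self.proximal) + self.distal


@dataclass(frozen=True)
class StagePreset:
    """Generator parameter bundle emulating one genotype x embryo stage."""

    name: str
    abundances: dict[str, GeneAbundance]
    n_reads: int = 20_000
    read_length: int = 100
    polya_capture_rate: float = 0.1
    tail_length: tuple[float, float] = (30.0, 5.0)
    internal_priming_rate: float = 0.02
    base_error_rate: float = 0.001
    cleavage_jitter_sd: float = 2.0
    seed: int = 0
    stage: str = ""
    genotype: str = ""

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for r in (self.polya_capture_rate, self.internal_priming_rate, self.base_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        vals = [a for ga in self.abundances.values() for a in (*ga.proximal, ga.distal)]
        if any(v < 0 for v in vals):
            raise ValueError("abundances must be >= 0")
        if vals and not any(v > 0 for v in vals):
            raise ValueError("abundance vector is all zero")

    def replace(self, **kw) -> "StagePreset":
        return dataclasses.replace(self, **kw)


def _flc_preset(name, prox_total, distal, ref, stage, genotype, **kw) -> StagePreset:
    return StagePreset(
        name=name,
        abundances={
            "FLC": GeneAbundance(proximal=(prox_total / 3,) * 3, distal=distal),
            "RPL": GeneAbundance(proximal=(), distal=ref),
        },
        stage=stage,
        genotype=genotype,
        **kw,
    )


def _build_presets() -> dict[str, StagePreset]:
    presets: dict[str, StagePreset] = {}

    # Col-0 embryo stage series: the proximal share starts above 80%, crosses
    # parity around the early heart stage and is extinct by mature green.
    # The three anchored stages carry the printed values; intermediate stages
    # are interpolated. FLC totals trace a rise-then-fall trajectory; the
    # reference gene is constant.
    series = [
        ("preglobular", 0.82, 1.00),
        ("globular", 0.70, 1.20),
        ("earlyheart", 0.50, 1.50),
        ("lateheart", 0.35, 1.20),
        ("earlytorpedo", 0.22, 0.90),
        ("latetorpedo", 0.12, 0.60),
        ("bentcotyledon", 0.04, 0.40),
        ("maturegreen", 0.00, 0.30),
    ]
    for stage, frac, total in series:
        presets[f"fig1c-col0-{stage}"] = _flc_preset(
            f"fig1c-col0-{stage}",
            prox_total=frac * total,
            distal=(1 - frac) * total,
            ref=2.0 if stage != "preglobular" else 1.0,
            stage=stage,
            genotype="Col-0",
        )

    # Genotype pair calibrated to the printed early-heart isoform abundances
    # (proximal 1.0 / distal 0.696 arbitrary units in Col-0 vs 0.5 / 6.96 in
    # Col FRI, i.e. total fold 4.4, distal fold 10, proximal fold 0.5). The
    # reference-gene abundance is set so the summed count/length rate is the
    # same in both samples (constant-transcriptome TPM assumption): with
    # FLC effective length 1900 and RPL 1000, a common rate budget of 0.013
    # gives RPL = 1000*(0.013 - FLC_total/1900).
    flc_len, rpl_len, rate_budget = 1900.0, 1000.0, 0.013
    for name, prox, dist, genotype in [
        ("fig1e-col0-earlyheart", 1.0, 0.696, "Col-0"),
        ("fig1e-colfri-earlyheart", 0.5, 6.96, "Col FRI"),
    ]:
        ref = rpl_len * (rate_budget - (prox + dist) / flc_len)
        presets[name] = _flc_preset(
            name, prox_total=prox, distal=dist, ref=ref,
            stage="earlyheart", genotype=genotype, polya_capture_rate=0.15,
        )

    # Calibrated to the 20:1 distal:proximal poly(A)-read ratio in Col FRI.
    presets["fig1f-colfri-earlyheart"] = _flc_preset(
        "fig1f-colfri-earlyheart", prox_total=1.0, distal=20.0, ref=4.0,
        stage="earlyheart", genotype="Col FRI", polya_capture_rate=0.15,
    )

    # FCA overexpression: proximal-shifted relative to Col-0 early heart.
    presets["fca-oe-earlyheart"] = _flc_preset(
        "fca-oe-earlyheart", prox_total=1.5, distal=0.5, ref=2.0,
        stage="earlyheart", genotype="35S::FCA",
    )
    return presets


PRESETS: dict[str, StagePreset] = _build_presets()

#: Names of the eight Col-0 embryo-stage presets, in developmental order.
COL0_STAGE_SERIES: tuple[str, ...] = tuple(
    f"fig1c-col0-{s}"
    for s in (
        "preglobular", "globular", "earlyheart", "lateheart",
        "earlytorpedo", "latetorpedo", "bentcotyledon", "maturegreen",
    )
)


def get_preset(name: str) -> StagePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {', '.join(sorted(PRESETS))}") from None


# --------------------------------------------------------------------------
# genome construction


def gene_models_from_spec(spec: GeneSpec, chrom: str) -> GeneModel:
    """Annotation implied by a gene spec: one full-length (distal) isoform
    with the spliced exon structure, plus one intron-retained truncated
    (proximal) isoform per proximal cleavage site."""
    gene = GeneModel(spec.gene_id, chrom, spec.strand, spec.start, spec.end)
    gene.transcripts.append(
        TranscriptModel(f"{spec.gene_id}.d", spec.gene_id, chrom, spec.strand, spec.exons)
    )
    # Proximal isoforms ordered 5' -> 3' along the transcript.
    prox = sorted(spec.proximal_pas, reverse=spec.strand == "-")
    for i, pas in enumerate(prox, start=1):
        if spec.strand == "+":
            exon = (spec.start, pas)
        else:
            exon = (pas, spec.end)
        gene.transcripts.append(
            TranscriptModel(f"{spec.gene_id}.p{i}", spec.gene_id, chrom, spec.strand, (exon,))
        )
    return gene


def _sanitize_guard_band(seq: np.ndarray, spec: GeneSpec, rng: np.random.Generator) -> None:
    """Remove transcript-orientation adenosine around each declared cleavage
    site so the internal-priming filter can never discard a true site and
    jitter extensions never add templated A's to a clip."""
    bad = b"A" if spec.strand == "+" else b"T"
    repl = np.frombuffer(b"CGT" if spec.strand == "+" else b"ACG", dtype="S1")
    for pas in (*spec.proximal_pas, spec.distal_pas):
        if spec.strand == "+":
            lo, hi = pas - GUARD_UP, pas + GUARD_DOWN
        else:
            lo, hi = pas - GUARD_DOWN, pas + GUARD_UP
        lo = max(lo, 1)
        window = seq[lo - 1 : hi]
        mask = window == bad
        window[mask] = rng.choice(repl, size=int(mask.sum()))


def build_genome(spec: GenomeSpec, seed: int, out_dir) -> tuple[Path, Path]:
    """Write the genome FASTA and the GFF3 annotation; returns their paths.

    Deterministic: identical (spec, seed) gives byte-identical files.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=spec.chrom_length)
    ts, tl = spec.a_tract
    seq[ts - 1 : ts - 1 + tl] = b"A"
    for g in spec.genes:
        _sanitize_guard_band(seq, g, rng)
    fasta_path = out_dir / "genome.fa"
    write_fasta(fasta_path, [(spec.chrom_name, seq.tobytes().decode())])
    genes = {g.gene_id: gene_models_from_spec(g, spec.chrom_name) for g in spec.genes}
    gff_path = out_dir / "annotation.gff3"
    write_gff3(genes, gff_path)
    return fasta_path, gff_path


# --------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedSample:
    """Paths and ground truth of one simulated sample."""

    name: str
    sam_path: Path
    fastq_path: Path
    truth_path: Path
    truth: pd.DataFrame = field(repr=False, default=None)


def _isoform_blocks(tx: TranscriptModel) -> list[list[int]]:
    """Exon blocks in ascending genomic order, as mutable [start, end]."""
    return [list(e) for e in tx.exons]


def _span_to_blocks(blocks, strand: str, t_start: int, t_len: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval [t_start, t_start+t_len) onto
    genomic blocks (ascending). Transcript coordinate 0 is the 5' end."""
    order = blocks if strand == "+" else list(reversed(blocks))
    out = []
    offset = 0
    remaining = t_len
    for s, e in order:
        blen = e - s + 1
        if t_start >= offset + blen:
            offset += blen
            continue
        local = max(t_start - offset, 0)
        take = min(blen - local, remaining)
        if strand == "+":
            out.append((s + local, s + local + take - 1))
        else:
            out.append((e - local - take + 1, e - local))
        remaining -= take
        offset += blen
        if remaining == 0:
            break
    if remaining:
        raise ValueError("transcript interval exceeds isoform length")
    return sorted(out)


def _blocks_to_cigar(blocks, strand: str, tail_len: int) -> list[tuple[int, int]]:
    """CIGAR tuples (pysam codes) for aligned genomic blocks plus an optional
    terminal soft clip on the transcript 3' side."""
    ops: list[tuple[int, int]] = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None:
            ops.append((3, s - prev_end - 1))  # N
        ops.append((0, e - s + 1))  # M
        prev_end = e
    if tail_len:
        if strand == "+":
            ops.append((4, tail_len))  # S at genomic right
        else:
            ops.insert(0, (4, tail_len))  # S at genomic left
    return ops


def _genome_slice(chrom_seq: str, blocks) -> str:
    return "".join(chrom_seq[s - 1 : e] for s, e in blocks)


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    k = rng.binomial(len(read), rate)
    if k == 0:
        return read
    arr = list(read)
    for pos in rng.integers(0, len(read), size=k):
        alt = "ACGT".replace(arr[pos], "")
        arr[pos] = alt[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    fasta_path,
    gff3_path,
    preset: StagePreset,
    out_dir,
    seed: int | None = None,
    sample_name: str | None = None,
) -> SimulatedSample:
    """Simulate one sample's stranded reads from a preset.

    Writes coordinate-sorted SAM, FASTQ (sequencing orientation, Phred+33)
    and a truth-table TSV into ``out_dir``. Deterministic for identical
    (genome, preset, seed).
    """
    preset.validate()
    seed = preset.seed if seed is None else seed
    sample_name = sample_name or preset.name
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    fasta = Fasta(str(fasta_path))
    chrom = list(fasta.keys())[0]
    chrom_seq = str(fasta[chrom][:])
    genes = load_gff3(gff3_path)

    # Enumerate isoforms with abundances, in a fixed order.
    isoforms = []  # (iso_id, gene, tx, cleavage_pos, abundance)
    for gid in sorted(preset.abundances):
        if gid not in genes:
            raise ValueError(f"preset references gene {gid!r} absent from the annotation")
        gene = genes[gid]
        ab = preset.abundances[gid]
        prox_txs = sorted(
            (t for t in gene.transcripts if t.transcript_id.rsplit(".", 1)[1].startswith("p")),
            key=lambda t: t.transcript_id,
        )
        if len(prox_txs) != len(ab.proximal):
            raise ValueError(
                f"{gid}: preset has {len(ab.proximal)} proximal abundances for "
                f"{len(prox_txs)} annotated proximal isoforms"
            )
        for t, a in zip(prox_txs, ab.proximal):
            isoforms.append((t.transcript_id, gene, t, t.three_prime_end, a))
        distal = next(t for t in gene.transcripts if t.transcript_id.endswith(".d"))
        isoforms.append((distal.transcript_id, gene, distal, distal.three_prime_end, ab.distal))

    weights = np.array([a for *_, a in isoforms], dtype=float)
    if preset.n_reads > 0 and weights.sum() <= 0:
        raise ValueError("abundance vector is all zero")

    read_len = preset.read_length
    mean_tail, sd_tail = preset.tail_length
    max_tail = read_len - 20
    records = []  # (pos0, read_id, flag, cigar, sam_seq, fastq_seq, truth row)

    counts = (
        rng.multinomial(preset.n_reads, weights / weights.sum())
        if preset.n_reads > 0
        else np.zeros(len(isoforms), dtype=int)
    )
    n_true_tail = 0
    for (iso_id, gene, tx, pas, _a), n_iso in zip(isoforms, counts):
        if n_iso == 0:
            continue
        L = tx.length
        if L < read_len:
            raise ValueError(f"isoform {iso_id} shorter ({L}) than the read length {read_len}")
        strand = tx.strand
        blocks = _isoform_blocks(tx)
        terminal = rng.random(n_iso) < preset.polya_capture_rate
        starts = rng.integers(0, L - read_len + 1, size=n_iso)
        tails = np.clip(
            np.rint(rng.normal(mean_tail, sd_tail, size=n_iso)).astype(int),
            MIN_TAIL_LEN,
            max_tail,
        )
        jitters = np.clip(
            np.rint(rng.normal(0.0, preset.cleavage_jitter_sd, size=n_iso)).astype(int),
            -JITTER_MAX,
            JITTER_MAX,
        )
        for i in range(n_iso):
            read_id = f"{sample_name}:{iso_id}:{i:06d}"
            if terminal[i]:
                n_true_tail += 1
                tail_len = int(tails[i])
                delta = int(jitters[i])
                # Jitter shifts the cleavage site along the genome; the
                # terminal exon block is extended/trimmed accordingly.
                jblocks = [list(b) for b in blocks]
                if strand == "+":
                    jblocks[-1][1] += delta
                    cleave = jblocks[-1][1]
                else:
                    jblocks[0][0] -= delta
                    cleave = jblocks[0][0]
                templated = read_len - tail_len
                eff_len = L + delta
                rblocks = _span_to_blocks(jblocks, strand, eff_len - templated, templated)
                gseq = _genome_slice(chrom_seq, rblocks)
                tseq = gseq if strand == "+" else revcomp(gseq)
                read = tseq + "A" * tail_len
                truth = (read_id, iso_id, gene.gene_id, True, tail_len, cleave, False)
            else:
                tail_len = 0
                rblocks = _span_to_blocks(blocks, strand, int(starts[i]), read_len)
                gseq = _genome_slice(chrom_seq, rblocks)
                read = gseq if strand == "+" else revcomp(gseq)
                truth = (read_id, iso_id, gene.gene_id, False, 0, -1, False)
            read = _apply_errors(read, rng, preset.base_error_rate)
            sam_seq = read if strand == "+" else revcomp(read)
            cigar = _blocks_to_cigar(rblocks, strand, tail_len)
            flag = 0 if strand == "+" else 16
            records.append((rblocks[0][0] - 1, read_id, flag, cigar, sam_seq, read, truth))

    # Internal-priming artifacts: apparent tail reads abutting the A-tract.
    # Emitted at `internal_priming_rate` per true poly(A) read, as extra
    # reads on top of n_reads.
    a_start = None
    n_art = rng.binomial(n_true_tail, preset.internal_priming_rate) if n_true_tail else 0
    if n_art:
        # Locate the planted tract: longest A-run outside genes is at the
        # spec-declared position; the caller supplies it via the FASTA, so we
        # find it as the first run of >= 10 A's outside any gene.
        a_start = _find_a_tract(chrom_seq, genes)
    for i in range(n_art):
        tail_len = int(
            np.clip(round(rng.normal(mean_tail, sd_tail)), MIN_TAIL_LEN, max_tail)
        )
        templated = read_len - tail_len
        rblocks = [(a_start - templated, a_start - 1)]
        gseq = _genome_slice(chrom_seq, rblocks)
        read = _apply_errors(gseq + "A" * tail_len, rng, preset.base_error_rate)
        read_id = f"{sample_name}:artifact:{i:06d}"
        cigar = _blocks_to_cigar(rblocks, "+", tail_len)
        truth = (read_id, "artifact", "", False, tail_len, a_start - 1, True)
        records.append((rblocks[0][0] - 1, read_id, 0, cigar, read, read, truth))

    records.sort(key=lambda r: (r[0], r[1]))

    sam_path = out_dir / f"{sample_name}.sam"
    fastq_path = out_dir / f"{sample_name}.fastq"
    truth_path = out_dir / f"{sample_name}.truth.tsv"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": len(chrom_seq)}]}
    )
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, open(
        fastq_path, "w"
    ) as fq:
        for pos0, read_id, flag, cigar, sam_seq, fq_seq, _truth in records:
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = sam_seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(sam_seq))
            sam.write(a)
            fq.write(f"@{read_id}\n{fq_seq}\n+\n{'I' * len(fq_seq)}\n")

    truth = pd.DataFrame(
        [r[6] for r in records],
        columns=[
            "read_id",
            "isoform",
            "gene_id",
            "has_untemplated_tail",
            "tail_length",
            "true_cleavage_pos",
            "is_internal_priming_artifact",
        ],
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedSample(sample_name, sam_path, fastq_path, truth_path, truth)


def _find_a_tract(chrom_seq: str, genes: dict[str, GeneModel], min_len: int = 10) -> int:
    """1-based start of the longest intergenic A-run of >= min_len bases.

    The planted tract is the longest A-homopolymer on the chromosome by
    construction; taking the longest (ties: leftmost) recovers it without
    the spec object in hand.
    """
    spans = sorted((g.start, g.end) for g in genes.values())
    best_pos, best_len = None, 0
    i, n = 0, len(chrom_seq)
    while i < n:
        if chrom_seq[i] == "A":
            j = i
            while j < n and chrom_seq[j] == "A":
                j += 1
            run, pos = j - i, i + 1
            if run >= min_len and run > best_len and not any(s <= pos <= e for s, e in spans):
                best_pos, best_len = pos, run
            i = j
        else:
            i += 1
    if best_pos is None:
        raise ValueError("no intergenic A-tract found in the genome")
    return best_pos
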