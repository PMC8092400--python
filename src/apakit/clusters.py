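"""Internal-priming filtering and poly(A) cluster construction.

Cleavage events from all samples are pooled, events whose downstream genomic
window is adenosine-rich are discarded as oligo(dT) internal-priming
artifacts, and the survivors are merged into clusters by single linkage.
Clusters are then classified as proximal (inside a gene body), distal (at a
gene's annotated 3' end) or intergenic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dnautil import longest_run, revcomp
from .gffio import GeneModel


@dataclass(frozen=True)
class IPFilterParams:
    """Thresholds for the genomic A-content filter downstream of a cleavage
    site. An event is discarded when the window's A fraction exceeds
    max_a_fraction or it contains a run of at least max_a_run A's — the
    signature of oligo(dT) priming on a templated A-tract rather than a real
    poly(A) tail."""

    window_len: int = 10
    max_a_fraction: float = 0.7
    max_a_run: int = 6

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0.0 <= self.max_a_fraction <= 1.0:
            raise ValueError("max_a_fraction must lie in [0, 1]")
        if self.max_a_run < 1:
            raise ValueError("max_a_run must be >= 1")


@dataclass(frozen=True)
class CleavageEvent:
    chrom: str
    strand: str
    pos: int  # 1-based
    sample: str


@dataclass
class PolyACluster:
    """A merged genomic interval of cleavage positions."""

    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    position_counts: dict[int, int] = field(default_factory=dict)
    sample_counts: dict[str, int] = field(default_factory=dict)
    cluster_class: str | None = None  # proximal / distal / intergenic
    gene_id: str | None = None

    @property
    def total(self) -> int:
        return sum(self.sample_counts.values())

    @property
    def summit(self) -> int:
        return summit(self)


def internal_priming_check(
    genome: Mapping[str, str],
    chrom: str,
    strand: str,
    pos: int,
    params: IPFilterParams = IPFilterParams(),
) -> bool:
    """True = keep the event, False = discard as internal priming.

    The window is the ``window_len`` bases immediately downstream of ``pos``
    in transcript orientation (reverse complemented on the minus strand),
    truncated at the chromosome edge. An empty window keeps the event.
    """
    seq = genome[chrom]
    if strand == "+":
        window = seq[pos : pos + params.window_len]
    else:
        window = revcomp(seq[max(pos - 1 - params.window_len, 0) : pos - 1])
    if not window:
        return True
    a_frac = window.count("A") / len(window)
    if a_frac > params.max_a_fraction:
        return False
    if longest_run(window, "A") >= params.max_a_run:
        return False
    return True


def filter_internal_priming(
    events: Iterable[CleavageEvent],
    genome: Mapping[str, str],
    params: IPFilterParams = IPFilterParams(),
) -> tuple[list[CleavageEvent], int]:
    """Apply the filter per event (before clustering, so a cluster never
    mixes filtered and unfiltered evidence). Returns (kept, n_discarded)."""
    kept, discarded = [], 0
    for ev in events:
        if internal_priming_check(genome, ev.chrom, ev.strand, ev.pos, params):
            kept.append(ev)
        else:
            discarded += 1
    return kept, discarded


def build_clusters(
    events: Sequence[CleavageEvent], merge_dist: int = 25
) -> list[PolyACluster]:
    """Single-linkage merge of cleavage positions per chromosome and strand.

    Consecutive sorted positions at most ``merge_dist`` bases apart join the
    same cluster; the cluster interval spans its member positions and counts
    are accumulated per sample.
    """
    by_key: dict[tuple[str, str], list[CleavageEvent]] = defaultdict(list)
    for ev in events:
        by_key[(ev.chrom, ev.strand)].append(ev)
    clusters: list[PolyACluster] = []
    for (chrom, strand) in sorted(by_key):
        evs = sorted(by_key[(chrom, strand)], key=lambda e: e.pos)
        current: list[CleavageEvent] = []
        for ev in evs:
            if current and ev.pos - current[-1].pos > merge_dist:
                clusters.append(_make_cluster(chrom, strand, current))
                current = []
            current.append(ev)
        if current:
            clusters.append(_make_cluster(chrom, strand, current))
    return clusters


def _make_cluster(chrom: str, strand: str, members: list[CleavageEvent]) -> PolyACluster:
    pos_counts = Counter(e.pos for e in members)
    samp_counts = Counter(e.sample for e in members)
    return PolyACluster(
        chrom=chrom,
        strand=strand,
        start=members[0].pos,
        end=members[-1].pos,
        position_counts=dict(pos_counts),
        sample_counts=dict(samp_counts),
    )


def summit(cluster: PolyACluster) -> int:
    """Most-supported position; ties break toward the transcript 5' side
    (lowest coordinate on '+', highest on '-')."""
    best = max(cluster.position_counts.values())
    candidates = [p for p, c in cluster.position_counts.items() if c == best]
    return min(candidates) if cluster.strand == "+" else max(candidates)


def classify_cluster(
    cluster: PolyACluster,
    genes: Mapping[str, GeneModel],
    terminator_window: int = 100,
) -> tuple[str, str | None]:
    """Classify a cluster against gene models.

    distal: summit within ``terminator_window`` bases of a same-strand
    gene's annotated distal 3' end (the longest isoform's terminus);
    proximal: summit inside a same-strand gene body upstream of that window;
    intergenic: anything else. Among several candidate genes the one with
    the nearest annotated 3' end wins.
    """
    s = summit(cluster)
    candidates = []
    for g in genes.values():
        if g.chrom != cluster.chrom or g.strand != cluster.strand:
            continue
        dist3 = abs(s - g.three_prime_end)
        if dist3 <= terminator_window:
            candidates.append((dist3, g.gene_id, "distal"))
        elif g.start <= s <= g.end:
            candidates.append((dist3, g.gene_id, "proximal"))
    if not candidates:
        return "intergenic", None
    _, gene_id, cls = min(candidates)
    return cls, gene_id


def classify_clusters(
    clusters: Iterable[PolyACluster],
    genes: Mapping[str, GeneModel],
    terminator_window: int = 100,
) -> list[PolyACluster]:
    out = []
    for c in clusters:
        c.cluster_class, c.gene_id = classify_cluster(c, genes, terminator_window)
        out.append(c)
    return out


def clusters_to_bed_rows(clusters: Sequence[PolyACluster]):
    """BED6 rows (name = gene:class:index, score = total count)."""
    per_gene_index: Counter = Counter()
    for c in clusters:
        gid = c.gene_id or "intergenic"
        per_gene_index[gid] += 1
        name = f"{gid}:{c.cluster_class or 'unclassified'}:{per_gene_index[gid]}"
        yield (c.chrom, c.start, c.end, name, c.total, c.strand)


def cluster_id(cluster: PolyACluster) -> str:
    return f"{cluster.chrom}:{cluster.start}-{cluster.end}:{cluster.strand}"
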