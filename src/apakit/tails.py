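"""Calling untemplated 3'-terminal poly(A) tails from alignment records.

A read provides evidence for a cleavage/polyadenylation event when its
alignment ends in a soft-clipped segment on the transcript-orientation 3'
side and that segment is long and adenosine-rich enough. The genomic
coordinate it supports is the last templated (aligned) base in transcript
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pysam

from .dnautil import revcomp

_SOFT_CLIP = 4
_REF_CONSUMING_QUERY = {0, 7, 8}  # M, =, X


@dataclass(frozen=True)
class TailParams:
    """Acceptance thresholds for a soft clip to count as a poly(A) tail.

    min_clip_len of 4 rejects single-base clip noise while keeping short
    genuine tails; min_purity of 0.8 tolerates one sequencing error in a
    five-base clip. Both are configurable everywhere they are used.
    """

    min_clip_len: int = 4
    min_purity: float = 0.8
    count_base: str = "A"

    def __post_init__(self):
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")
        if not 0.0 < self.min_purity <= 1.0:
            raise ValueError("min_purity must lie in (0, 1]")


@dataclass(frozen=True)
class ClipSegment:
    """A terminal soft clip in transcript orientation."""

    sequence: str
    side: str = "3prime"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TailCall:
    """One read's accepted untemplated poly(A) evidence."""

    read_id: str
    chrom: str
    strand: str
    cleavage_pos: int  # 1-based, last templated base in transcript orientation
    clip_length: int
    a_fraction: float


@dataclass
class TailTally:
    """Exact partition of every record seen by the scanner."""

    seen: int = 0
    accepted: int = 0
    no_clip: int = 0
    rejected_by_length: int = 0
    rejected_by_purity: int = 0
    skipped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def extract_terminal_clip(aln: pysam.AlignedSegment) -> ClipSegment | None:
    """Soft clip at the read's transcript-orientation 3' end, or None.

    Forward-strand alignments: the rightmost clip, as stored. Reverse-strand
    alignments: the leftmost clip, reverse complemented (SAM stores SEQ in
    genome-forward orientation).
    """
    if aln.is_unmapped or not aln.cigartuples:
        return None
    cig = aln.cigartuples
    seq = aln.query_sequence
    if aln.is_reverse:
        op, n = cig[0]
        if op != _SOFT_CLIP:
            return None
        return ClipSegment(revcomp(seq[:n]))
    op, n = cig[-1]
    if op != _SOFT_CLIP:
        return None
    return ClipSegment(seq[-n:])


def call_tail(clip: ClipSegment, params: TailParams = TailParams()) -> tuple[bool, float]:
    """Accept/reject a clip as an untemplated poly(A) tail.

    Returns (accepted, a_fraction); the fraction is reported for rejected
    clips too so rejection reasons can be tallied.
    """
    a_fraction = clip.sequence.count(params.count_base) / clip.length
    ok = clip.length >= params.min_clip_len and a_fraction >= params.min_purity
    return ok, a_fraction


def cleavage_position(aln: pysam.AlignedSegment) -> tuple[str, str, int]:
    """(chrom, strand, pos): genomic coordinate (1-based) of the final
    aligned base at the transcript-orientation 3' end."""
    strand = "-" if aln.is_reverse else "+"
    pos = aln.reference_start + 1 if aln.is_reverse else aln.reference_end
    return aln.reference_name, strand, pos


def scan_alignments(
    path_or_file, params: TailParams = TailParams()
) -> tuple[list[TailCall], TailTally]:
    """Scan a SAM/BAM stream and emit one TailCall per accepted read.

    Secondary and supplementary alignments, unmapped and CIGAR-less records
    are skipped (tallied). A missing @SQ header is rejected outright.
    """
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    af = pysam.AlignmentFile(str(path_or_file), "r", check_sq=False) if own else path_or_file
    try:
        if not af.header.to_dict().get("SQ"):
            raise ValueError(f"{getattr(af, 'filename', path_or_file)}: missing @SQ header")
        calls: list[TailCall] = []
        tally = TailTally()
        for aln in af:
            tally.seen += 1
            if (
                aln.is_secondary
                or aln.is_supplementary
                or aln.is_unmapped
                or not aln.cigartuples
            ):
                tally.skipped += 1
                continue
            clip = extract_terminal_clip(aln)
            if clip is None:
                tally.no_clip += 1
                continue
            if clip.length < params.min_clip_len:
                tally.rejected_by_length += 1
                continue
            ok, a_fraction = call_tail(clip, params)
            if not ok:
                tally.rejected_by_purity += 1
                continue
            tally.accepted += 1
            chrom, strand, pos = cleavage_position(aln)
            calls.append(
                TailCall(aln.query_name, chrom, strand, pos, clip.length, a_fraction)
            )
        return calls, tally
    finally:
        if own:
            af.close()


def write_tailcalls_tsv(calls: Iterable[TailCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tcleavage_pos\tclip_length\ta_fraction\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.chrom}\t{c.strand}\t{c.cleavage_pos}\t"
                f"{c.clip_length}\t{c.a_fraction:.4f}\n"
            )


def read_tailcalls_tsv(path) -> list[TailCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a tail-call TSV")
        for line in fh:
            rid, chrom, strand, pos, clen, afrac = line.rstrip("\n").split("\t")
            calls.append(TailCall(rid, chrom, strand, int(pos), int(clen), float(afrac)))
    return calls


def write_tailcalls_bed(calls: Iterable[TailCall], path) -> None:
    """BED6 of single-base cleavage positions; score = clip length."""
    from .gffio import write_bed6

    write_bed6(
        path,
        (
            (c.chrom, c.cleavage_pos, c.cleavage_pos, c.read_id, c.clip_length, c.strand)
            for c in calls
        ),
    )
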