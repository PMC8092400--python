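import pysam
import pytest
from pyfaidx import Fasta

from apakit import (
    build_genome,
    default_genome_spec,
    get_preset,
    load_gff3,
    simulate_and_analyze,
    simulate_reads,
)


@pytest.fixture(scope="session")
def genome(tmp_path_factory):
    """Default two-gene genome: paths, raw sequence and gene models."""
    out = tmp_path_factory.mktemp("genome")
    fasta_path, gff_path = build_genome(default_genome_spec(), seed=7, out_dir=out)
    fa = Fasta(str(fasta_path))
    chrom = list(fa.keys())[0]
    return {
        "fasta": fasta_path,
        "gff3": gff_path,
        "chrom": chrom,
        "seq": str(fa[chrom][:]),
        "genes": load_gff3(gff_path),
        "spec": default_genome_spec(),
    }


@pytest.fixture(scope="session")
def earlyheart_sim(genome, tmp_path_factory):
    """One simulated early-heart sample (proximal ~= distal), with truth."""
    out = tmp_path_factory.mktemp("sim_eh")
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=8000)
    return simulate_reads(genome["fasta"], genome["gff3"], preset, out, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """Full pipeline over two stages at small depth (shared cluster set)."""
    out = tmp_path_factory.mktemp("pipe")
    return simulate_and_analyze(
        [
            ("pg", "fig1c-col0-preglobular", 11, 8000),
            ("eh", "fig1c-col0-earlyheart", 12, 8000),
        ],
        out,
    )


def make_alignment(
    chrom="chr1",
    chrom_len=60000,
    query_name="r1",
    flag=0,
    pos0=1000,
    cigar=((0, 100),),
    seq=None,
):
    """Hand-build a single pysam record for unit tests."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = query_name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos0
    a.mapping_quality = 60
    a.cigartuples = list(cigar)
    qlen = sum(n for op, n in cigar if op in (0, 1, 4, 7, 8))
    a.query_sequence = seq if seq is not None else "C" * qlen
    return a
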