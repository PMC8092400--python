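"""Generator contracts: determinism, annotation shape, ground-truth
consistency and recovery of preset mixing fractions."""

import numpy as np
import pysam
import pytest

from apakit import (
    GeneAbundance,
    GeneSpec,
    GenomeSpec,
    build_genome,
    default_genome_spec,
    get_preset,
    load_gff3,
    simulate_reads,
)
from apakit.simulate import gene_models_from_spec


def test_build_genome_is_deterministic(tmp_path):
    spec = default_genome_spec()
    f1, g1 = build_genome(spec, seed=7, out_dir=tmp_path / "a")
    f2, g2 = build_genome(spec, seed=7, out_dir=tmp_path / "b")
    assert f1.read_bytes() == f2.read_bytes()
    assert g1.read_bytes() == g2.read_bytes()


def test_flc_gene_has_three_proximal_plus_one_distal_mrna(genome):
    flc = genome["genes"]["FLC"]
    assert len(flc.transcripts) == 4
    prox = [t for t in flc.transcripts if ".p" in t.transcript_id]
    assert len(prox) == 3
    # proximal isoforms are single-exon intron-retained truncations
    assert all(len(t.exons) == 1 for t in prox)


def test_planted_a_tract_is_all_a(genome):
    start, length = genome["spec"].a_tract
    assert genome["seq"][start - 1 : start - 1 + length] == "A" * length


def test_overlapping_genes_rejected():
    g1 = GeneSpec("G1", "+", ((100, 200), (300, 400)), (), 400)
    g2 = GeneSpec("G2", "+", ((350, 600),), (), 600)
    spec = GenomeSpec(chrom_length=5000, genes=(g1, g2), a_tract=(1000, 20))
    with pytest.raises(ValueError, match="G1.*G2"):
        build_genome(spec, seed=1, out_dir="/tmp/never")


def test_proximal_site_strictly_inside_gene_body():
    # a "proximal" site at the distal terminus itself is rejected
    with pytest.raises(ValueError, match="outside the gene body"):
        GeneSpec("G", "+", ((100, 1000),), (1000,), 1000).validate()
    with pytest.raises(ValueError, match="outside the gene body"):
        GeneSpec("G", "-", ((100, 1000),), (100,), 100).validate()


def test_simulate_is_deterministic(genome, tmp_path):
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=2000)
    s1 = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path / "a", seed=3)
    s2 = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path / "b", seed=3)
    for a, b in [(s1.sam_path, s2.sam_path), (s1.fastq_path, s2.fastq_path), (s1.truth_path, s2.truth_path)]:
        assert a.read_bytes() == b.read_bytes()


def test_capture_rate_zero_yields_no_tail_reads(genome, tmp_path):
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=3000, polya_capture_rate=0.0)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=5)
    assert not sim.truth.has_untemplated_tail.any()
    assert not sim.truth.is_internal_priming_artifact.any()


def test_zero_reads_is_valid_and_empty(genome, tmp_path):
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=0)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=5)
    assert len(sim.truth) == 0
    with pysam.AlignmentFile(str(sim.sam_path), "r", check_sq=False) as af:
        assert sum(1 for _ in af) == 0


def test_all_zero_abundance_rejected(genome, tmp_path):
    preset = get_preset("fig1c-col0-earlyheart").replace(
        abundances={
            "FLC": GeneAbundance((0.0, 0.0, 0.0), 0.0),
            "RPL": GeneAbundance((), 0.0),
        }
    )
    with pytest.raises(ValueError, match="all zero"):
        simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=5)


def test_record_count_conservation(earlyheart_sim):
    """SAM records = FASTQ records = truth rows."""
    with pysam.AlignmentFile(str(earlyheart_sim.sam_path), "r", check_sq=False) as af:
        n_sam = sum(1 for _ in af)
    n_fastq = sum(1 for line in open(earlyheart_sim.fastq_path) if line.startswith("@"))
    assert n_sam == n_fastq == len(earlyheart_sim.truth)
    assert earlyheart_sim.truth.read_id.is_unique


def test_templated_portion_matches_genome(genome, tmp_path):
    """With zero base errors, every aligned block equals the genome substring."""
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=1500, base_error_rate=0.0)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=9)
    seq = genome["seq"]
    with pysam.AlignmentFile(str(sim.sam_path), "r", check_sq=False) as af:
        for aln in af:
            expected = "".join(seq[s:e] for s, e in aln.get_blocks())
            assert aln.query_alignment_sequence == expected


def test_mixing_fractions_recovered_at_depth(genome, tmp_path):
    """Per-isoform read fractions converge to molar fractions (3 binomial SD)."""
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=50_000)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=17)
    truth = sim.truth[~sim.truth.is_internal_priming_artifact]
    n = len(truth)
    ab = preset.abundances
    total = sum(ga.total for ga in ab.values())
    expected = {
        "FLC.p1": ab["FLC"].proximal[0], "FLC.p2": ab["FLC"].proximal[1],
        "FLC.p3": ab["FLC"].proximal[2], "FLC.d": ab["FLC"].distal,
        "RPL.d": ab["RPL"].distal,
    }
    obs = truth.isoform.value_counts()
    for iso, a in expected.items():
        p = a / total
        sd = np.sqrt(p * (1 - p) * n)
        assert abs(obs[iso] - p * n) <= 3 * sd, iso


def test_artifact_rate_matches_binomial(genome, tmp_path):
    preset = get_preset("fig1c-col0-earlyheart").replace(n_reads=10_000)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=23)
    n_tail = int(sim.truth.has_untemplated_tail.sum())
    n_art = int(sim.truth.is_internal_priming_artifact.sum())
    rate = preset.internal_priming_rate
    sd = np.sqrt(n_tail * rate * (1 - rate))
    assert abs(n_art - rate * n_tail) <= 3 * sd


def test_fig1f_truth_ratio_near_twenty(genome, tmp_path):
    """Distal:proximal tail-read ratio in the Col FRI preset's ground truth."""
    preset = get_preset("fig1f-colfri-earlyheart").replace(n_reads=50_000)
    sim = simulate_reads(genome["fasta"], genome["gff3"], preset, tmp_path, seed=1)
    tails = sim.truth[sim.truth.has_untemplated_tail & (sim.truth.gene_id == "FLC")]
    prox = (tails.isoform != "FLC.d").sum()
    dist = (tails.isoform == "FLC.d").sum()
    ratio = dist / prox
    # binomial error on the proximal count dominates
    assert abs(ratio - 20.0) <= 3 * ratio / np.sqrt(prox)


def test_gene_models_from_spec_minus_strand():
    g = GeneSpec("M", "-", ((100, 200), (300, 400)), (350,), 100)
    gene = gene_models_from_spec(g, "chr1")
    distal = gene.distal_transcript
    assert distal.three_prime_end == 100
    prox = [t for t in gene.transcripts if ".p" in t.transcript_id][0]
    assert prox.exons == ((350, 400),)
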