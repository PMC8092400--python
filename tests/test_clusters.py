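"""Cluster builder: internal-priming filter, single-linkage merging against a
brute-force oracle, summits and proximal/distal classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit import (
    CleavageEvent,
    IPFilterParams,
    build_clusters,
    classify_cluster,
    internal_priming_check,
    summit,
)
from apakit.clusters import PolyACluster
from apakit.dnautil import revcomp


def _genome_with_window(window: str, pos: int = 500) -> dict:
    """Plus-strand genome whose bases downstream of `pos` are `window`."""
    seq = "C" * pos + window + "C" * 100
    return {"chr1": seq}


class TestInternalPrimingCheck:
    def test_all_a_window_discarded(self):
        g = _genome_with_window("AAAAAAAAAA")
        assert internal_priming_check(g, "chr1", "+", 500) is False

    def test_low_a_window_kept(self):
        # 3 A's, fraction 0.3, max run 1
        g = _genome_with_window("ACGTACGTAC")
        assert internal_priming_check(g, "chr1", "+", 500) is True

    def test_a_run_of_six_discarded(self):
        g = _genome_with_window("AAAAAAGCGT")
        assert internal_priming_check(g, "chr1", "+", 500) is False

    def test_minus_strand_window_is_upstream_revcomp(self):
        # downstream of a minus-strand event lies at lower coordinates,
        # and genomic T reads as A in transcript orientation
        seq = "C" * 490 + "T" * 10 + "C" * 100
        g = {"chr1": seq}
        assert internal_priming_check(g, "chr1", "-", 501) is False
        assert internal_priming_check(g, "chr1", "+", 501) is True

    def test_window_truncated_at_chromosome_edge(self):
        g = {"chr1": "C" * 500}
        assert internal_priming_check(g, "chr1", "+", 500) is True


def _events(positions, strand="+", chrom="chr1", sample="s"):
    return [CleavageEvent(chrom, strand, p, sample) for p in positions]


def brute_force_clusters(positions, merge_dist):
    """O(n^2) transitive closure: the independent clustering oracle."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= merge_dist:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


class TestBuildClusters:
    def test_worked_example(self):
        clusters = build_clusters(_events([1000, 1005, 1020, 1060]), merge_dist=25)
        assert len(clusters) == 2
        (c1, c2) = clusters
        assert (c1.start, c1.end, c1.total) == (1000, 1020, 3)
        assert (c2.start, c2.end, c2.total) == (1060, 1060, 1)

    def test_empty_input(self):
        assert build_clusters([]) == []

    def test_per_sample_counts_accumulate(self):
        evs = _events([100, 105], sample="a") + _events([103], sample="b")
        (c,) = build_clusters(evs)
        assert c.sample_counts == {"a": 2, "b": 1}

    def test_strands_never_merge(self):
        evs = _events([100], strand="+") + _events([101], strand="-")
        assert len(build_clusters(evs)) == 2

    @settings(max_examples=100, deadline=None)
    @given(
        positions=st.lists(st.integers(1, 2000), min_size=1, max_size=200),
        merge_dist=st.integers(0, 60),
    )
    def test_matches_transitive_closure_oracle(self, positions, merge_dist):
        clusters = build_clusters(_events(positions), merge_dist)
        got = sorted(
            sorted(p for p, c in cl.position_counts.items() for _ in range(c))
            for cl in clusters
        )
        assert got == brute_force_clusters(positions, merge_dist)

    @settings(max_examples=50, deadline=None)
    @given(
        positions=st.lists(st.integers(1, 2000), min_size=1, max_size=100),
        merge_dist=st.integers(0, 60),
    )
    def test_partition_and_separation(self, positions, merge_dist):
        clusters = build_clusters(_events(positions), merge_dist)
        assert sum(c.total for c in clusters) == len(positions)
        bounds = sorted((c.start, c.end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            assert s2 - e1 > merge_dist


class TestSummit:
    def _cluster(self, counts, strand):
        return PolyACluster(
            "chr1", strand, min(counts), max(counts), position_counts=dict(counts)
        )

    def test_unique_mode(self):
        assert summit(self._cluster({1000: 3, 1005: 1}, "+")) == 1000

    def test_tie_breaks_five_prime_plus(self):
        assert summit(self._cluster({1000: 2, 1005: 2}, "+")) == 1000

    def test_tie_breaks_five_prime_minus(self):
        assert summit(self._cluster({1000: 2, 1005: 2}, "-")) == 1005


class TestClassify:
    def _cluster_at(self, pos, strand="+"):
        return PolyACluster("chr1", strand, pos, pos, position_counts={pos: 1})

    def test_summit_at_annotated_end_is_distal(self, genome):
        cls, gid = classify_cluster(self._cluster_at(15000), genome["genes"])
        assert (cls, gid) == ("distal", "FLC")

    def test_summit_in_intron_one_is_proximal(self, genome):
        cls, gid = classify_cluster(self._cluster_at(10900), genome["genes"])
        assert (cls, gid) == ("proximal", "FLC")

    def test_a_tract_region_is_intergenic(self, genome):
        start, _ = genome["spec"].a_tract
        cls, gid = classify_cluster(self._cluster_at(start - 1), genome["genes"])
        assert (cls, gid) == ("intergenic", None)

    def test_strand_mismatch_is_intergenic(self, genome):
        # inside the FLC body but on the wrong strand
        cls, gid = classify_cluster(self._cluster_at(10900, strand="-"), genome["genes"])
        assert (cls, gid) == ("intergenic", None)

    def test_minus_strand_distal_end(self, genome):
        cls, gid = classify_cluster(self._cluster_at(30001, strand="-"), genome["genes"])
        assert (cls, gid) == ("distal", "RPL")


def test_filter_efficacy_on_simulation(genome, earlyheart_sim):
    """Planted artifacts are discarded; true tail events survive."""
    from apakit import scan_alignments

    calls, _ = scan_alignments(earlyheart_sim.sam_path)
    truth = earlyheart_sim.truth.set_index("read_id")
    g = {genome["chrom"]: genome["seq"]}
    params = IPFilterParams()
    kept = {
        c.read_id
        for c in calls
        if internal_priming_check(g, c.chrom, c.strand, c.cleavage_pos, params)
    }
    called = {c.read_id for c in calls}
    art = truth.index[truth.is_internal_priming_artifact]
    true_tail = truth.index[truth.has_untemplated_tail]
    art_called = [r for r in art if r in called]
    assert art_called, "no artifact reads reached the filter"
    assert sum(r in kept for r in art_called) / len(art_called) < 0.05
    tail_called = [r for r in true_tail if r in called]
    assert sum(r not in kept for r in tail_called) / len(tail_called) < 0.05
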