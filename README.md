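# apakit

Alternative-polyadenylation (APA) analysis of RNA-seq alignments: calling
untemplated 3′-terminal poly(A) tails from soft-clipped reads, filtering
internal-priming artifacts, clustering cleavage sites, classifying clusters
as proximal or distal, and quantifying isoform usage across developmental
stages and genotypes — together with a ground-truth read simulator so the
whole pipeline runs and is tested at desk scale, with no external data.

## The problem

In *Arabidopsis*, expression of the floral repressor *FLC* is set during
early embryogenesis by a tug-of-war over polyadenylation-site choice on the
nascent sense transcript: the repressor FCA promotes cleavage at **proximal**
sites inside the first intron (yielding truncated, non-functional isoforms),
while the activator FRIGIDA promotes use of the **distal** site at the
annotated 3′ end. Which site wins is visible in bulk RNA-seq: a read that
crosses the cleavage point carries a run of adenosines that is not in the
genome, and an aligner stores that run as a terminal soft clip. `apakit`
turns those soft clips into quantitative APA measurements:

- **Tail calling** — a read supports a cleavage event when its
  transcript-orientation 3′ soft clip has length ≥ `min_clip_len` (default
  4) and adenosine fraction ≥ `min_purity` (default 0.8). The supported
  coordinate is the last templated base.
- **Internal-priming filter** — an event is discarded when the genomic
  window downstream of the cleavage site (10 bases, transcript orientation)
  has A-fraction > 0.7 or an A-run ≥ 6: the signature of oligo(dT) priming
  on templated adenosines rather than a real poly(A) tail.
- **Clustering** — surviving cleavage positions from *all* samples are
  pooled and merged by single linkage (gap ≤ 25 bases), so samples are
  compared on one shared cluster set; each cluster gets a summit (modal
  position, ties toward 5′) and per-sample counts.
- **Classification** — a cluster is *distal* if its summit lies within 100
  bases of a same-strand gene's annotated 3′ end (longest isoform),
  *proximal* if it lies inside the gene body upstream of that window,
  *intergenic* otherwise.
- **Quantification** — per sample: cluster RPM (poly(A) reads per million
  mapped reads), gene TPM (reads on the exonic union / distal-isoform
  length, normalized to 10⁶), the poly(A) usage statistic
  log₂[(proximal RPM + ε)/(distal RPM + ε)], and isoform abundances
  obtained by splitting the gene TPM with the poly(A)-read mixing fraction
  *f* = proximal/(proximal+distal) — valid because every transcript
  contributes exactly one 3′ end, so *f* estimates the molar fraction.
- **Comparison** — fold changes of group means, differential flags by the
  strictly-more-than-twofold rule at adjusted *P* < 10⁻³, and significance
  ranking (a Welch *t* test on log TPM replicates with Benjamini–Hochberg
  adjustment stands in for a dedicated DE tool).

The simulator (`apakit.simulate`) builds a 60 kb genome containing an
*FLC*-like gene (three exons; three proximal sites in intron 1; one distal
terminator), a minus-strand reference gene, and a planted intergenic
A-tract; stage/genotype **presets** encode per-isoform molar abundances
calibrated to the embryo time series and genotype contrasts the pipeline is
expected to recover (see `docs/methods.md`).

## Worked example

Simulate a Col-0-like and a FRI-introgressed-like early-heart embryo sample
(20,000 reads each) and run the full pipeline:

```python
import tempfile
from apakit import simulate_and_analyze

res = simulate_and_analyze(
    [("col0", "fig1e-col0-earlyheart", 1, 20_000),
     ("fri",  "fig1e-colfri-earlyheart", 2, 20_000)],
    tempfile.mkdtemp(),
)
for c in res.clusters:
    print(c.strand, f"{c.start}-{c.end}", c.cluster_class, c.gene_id, c.sample_counts)
```

```
+ 10695-10704 proximal FLC {'col0': 68, 'fri': 29}
+ 10895-10906 proximal FLC {'col0': 70, 'fri': 27}
+ 11095-11105 proximal FLC {'col0': 68, 'fri': 29}
+ 14994-15006 distal   FLC {'col0': 152, 'fri': 1339}
- 29995-30007 distal   RPL {'col0': 2626, 'fri': 1649}
```

The three intron-1 proximal clusters and the distal terminator cluster of
the *FLC*-like gene are recovered, and the genotype contrast is visible
directly in the per-sample counts: proximal usage drops while distal usage
explodes in the FRI-like sample. Quantitatively
(`res.quants["col0"].gene_apa`, column meanings as above):

```
gene_id  proximal_reads  distal_reads  proximal_rpm  distal_rpm  log2_ratio  proximal_tpm  distal_tpm
    FLC             206           152     10272.265    7579.535       0.436     39640.815   29249.533
```

so in the Col-0-like sample proximal poly(A) reads roughly equal distal
reads (log₂ ratio 0.44). Comparing the two samples recovers the calibrated
genotype effects — total *FLC* TPM fold 4.41 (truth 4.4) and
distal-isoform fold 9.76 (truth 10) — already at this modest depth.

The same pipeline is scriptable from the shell:

```bash
apakit simulate --preset fig1c-col0-preglobular --seed 1 --out sim/
apakit call-tails --bam sim/fig1c-col0-preglobular.sam --out sim/pg
apakit cluster --tails sim/pg.tails.tsv --genome sim/genome.fa --gff sim/annotation.gff3 --out sim/pg
apakit run-all --config config.yaml --seed 1
```

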