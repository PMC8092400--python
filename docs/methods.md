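# Methods

This note documents the models and procedures implemented in `apakit`, the
parameters that matter, the design decisions that were genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Poly(A)-tail evidence model

A cleavage/polyadenylation event is inferred from a single aligned read when
the read carries a soft-clipped segment at its transcript-orientation 3′ end
(rightmost clip of a forward alignment; leftmost clip of a reverse
alignment, reverse complemented) that passes two thresholds:

| parameter | default | units | rationale |
|---|---|---|---|
| `min_clip_len` | 4 | bases | rejects 1–3-base clip noise while keeping short genuine tails |
| `min_purity` | 0.8 | fraction of A | tolerates one sequencing error in a five-base clip |

The event coordinate is the last templated base in transcript orientation
(highest reference position of a forward alignment, lowest of a reverse
one), computed by walking the CIGAR so spliced (N-containing) alignments are
handled. Secondary and supplementary records are skipped — one vote per read
— and the scanner's tally (`seen = accepted + no_clip + rejected_by_length +
rejected_by_purity + skipped`) is an exact partition, asserted in tests.

Untemplatedness is taken from the alignment's soft clip; the caller does not
re-check the clip against the genome. Genomically templated A-runs are
instead handled at the locus level by the internal-priming filter, which
keeps read-level and locus-level evidence separable. The clip must be
strictly terminal; a non-A linker between the alignment and the tail is not
modelled.

## Internal-priming filter

Oligo(dT) priming on a genomically encoded A-tract produces reads that look
exactly like tail reads but whose "tail" is templated just downstream of the
apparent cleavage site. An event is therefore discarded when the genomic
window `window_len` = 10 bases immediately downstream (transcript
orientation; reverse complemented on the minus strand; truncated at the
chromosome edge) has A-fraction > 0.7 **or** contains an A-run ≥ 6. The
filter runs per event, before clustering, so a cluster never mixes filtered
and unfiltered evidence. These thresholds are conventional APA practice and
are configurable everywhere.

## Clustering and classification

Cleavage positions exhibit microheterogeneity on the scale of a few bases,
so events pooled across **all** samples are merged per chromosome and strand
by single linkage with `merge_dist` = 25 bases (consecutive sorted positions
with gap ≤ 25 join). Pooling first and counting per sample second guarantees
that stages and genotypes are compared on one shared cluster set. The
implementation is checked against an O(n²) transitive-closure oracle on
random instances. A cluster's summit is its modal position, ties broken
toward the transcript 5′ side.

Classification against the annotation: the gene's distal 3′ end is defined
by its longest annotated isoform (ties toward the most 3′ terminus); a
summit within `terminator_window` = 100 bases of that end is *distal*, a
summit inside the gene body upstream of the window is *proximal*, anything
else *intergenic*; among overlapping same-strand genes the nearest annotated
3′ end wins.

## Quantification

* **RPM** uses the whole library (primary mapped reads) as denominator, not
  only poly(A) reads, so proximal and distal RPM remain comparable between
  samples with different tail-capture efficiency.
* **Gene TPM**: counts are primary mapped reads overlapping the gene's
  exonic union over all annotated isoforms (strand-aware; the proximal,
  intron-retained isoforms contribute their retained segment to the union),
  divided by the distal isoform's exonic length, renormalized to 10⁶.
  Per-sample TPM sums to 10⁶ within 10⁻⁶ relative (tested).
* **log₂ poly(A) ratio**: log₂[(proximal RPM + ε)/(distal RPM + ε)] with ε
  equal to one read in RPM units by default; ε = 0 is exact and finite
  whenever both sides are positive.
* **Isoform abundance**: proximal TPM = gene TPM × *f*, distal TPM =
  gene TPM × (1 − *f*), with *f* the proximal share of the gene's poly(A)
  cluster reads. The two outputs sum to the gene TPM exactly; with zero
  poly(A) reads they are emitted as missing.
* **Comparisons**: fold change is the simple ratio of group means (missing
  when the reference mean is zero); the differential flag requires fold
  change strictly greater than 2 (or strictly less than ½) **and** adjusted
  *P* strictly below 10⁻³. Significance comes from a Welch two-sample *t*
  test on log₂(TPM + 0.5) replicates with Benjamini–Hochberg adjustment — a
  deliberately plain stand-in that exercises the flagging and ranking logic;
  it is not a negative-binomial DE model and is labelled as such in the API.

## The synthetic benchmark

### Genome

A 60 kb chromosome of uniform random nucleotides containing: an *FLC*-like
plus-strand gene (exons 10,001–10,400 / 13,001–13,500 / 14,001–15,000;
proximal sites 10,700 / 10,900 / 11,100 inside intron 1, 200 bases apart so
they resolve into separate clusters; distal terminator 15,000), a
minus-strand two-exon reference gene (`RPL`, 3′ end 30,001, exonic length
1,000), and a 20-base intergenic A-tract at 45,001 for internal-priming
tests. The annotation carries one full-length spliced isoform plus one
single-exon intron-retained truncated isoform per proximal site (four mRNAs
for the *FLC*-like gene).

Around every declared cleavage site the builder plants a **guard band**
(internal-priming window + jitter margin, 33 bases) free of
transcript-orientation adenosine. This guarantees deterministically that
true sites survive the internal-priming filter and that jittered cleavage
positions never abut templated A's; it slightly idealizes real 3′ ends,
where genuine sites near A-rich sequence are occasionally lost.

### Read model

Reads (default length 100) are sampled per isoform proportionally to molar
abundance with uniform fragment starts. A fraction `polya_capture_rate`
(default 0.1) of each isoform's reads is its 3′-terminal fragment: its end
is the isoform's cleavage site plus a rounded-normal jitter (sd 2, clipped
at ±6 bases — cleavage microheterogeneity), and it carries an untemplated
A-run (truncated normal, mean 30, sd 5, minimum 4) encoded as a terminal
soft clip with the correct CIGAR and strand orientation. Base errors are
uniform substitutions at 10⁻³ per base. The library is stranded (read strand
reports transcript strand), which is what lets the pipeline keep sense and
antisense signal apart.

Internal-priming artifacts are emitted at `internal_priming_rate` = 0.02 per
true poly(A) read as *apparent* tail reads — templated portion ending at the
base before the A-tract, plus a pure-A soft clip. A literally fully
templated artifact read would carry no clip, would never be called, and
could therefore never exercise the downstream filter; modelling artifacts as
apparent tail reads at the tract boundary is what makes the filter's
false-positive behaviour measurable.

Sampling reads proportionally to molar abundance (rather than molar ×
length) is an idealization chosen to make the crude gene-level quantifier —
all reads on the exonic union over the distal length — an unbiased molar
estimator even when the isoform mix shifts; with length-weighted sampling a
union-count/single-length quantifier would confound abundance with isoform
length. The simulator is a test harness for the pipeline's logic, not a
physical model of library preparation: fragment-position biases, GC bias,
PCR duplicates, paired ends, quality-dependent errors and splice-site
sequence constraints at junctions are all out of scope, so passing tests
demonstrate correctness of the APA logic, not robustness to real library
artifacts.

### Presets

Each preset fixes per-isoform molar abundances (plus the reference gene) and
is calibrated, before any pipeline run, to one printed observation it must
let the pipeline recover:

| preset | calibration |
|---|---|
| `fig1c-col0-preglobular` | proximal share of *FLC* poly(A) reads = 0.82 |
| `fig1c-col0-earlyheart` | proximal ≈ distal |
| `fig1c-col0-maturegreen` | proximal abundance 0 (signal extinct) |
| `fig1e-col0-earlyheart` / `fig1e-colfri-earlyheart` | proximal:distal 1.0:0.696 vs 0.5:6.96 → total fold 4.4, distal fold 10, proximal fold 0.5 simultaneously |
| `fig1f-colfri-earlyheart` | distal:proximal poly(A) reads 20:1 |
| `fca-oe-earlyheart` | proximal-shifted relative to Col-0 |

The remaining five stages of the eight-stage Col-0 series interpolate the
proximal share between the anchored values (0.82 → 0.50 → 0), with a
rise-then-fall total-abundance trajectory; they exist to exercise the
stage-series machinery, not to assert printed numbers. The isoform-abundance
and ratio observations are not mutually consistent under a single molar
model, so the `fig1e` and `fig1f` presets are calibrated per observation.

Two further calibration choices matter. First, TPM is compositional, so the
expected gene-TPM fold between two presets depends on the rest of the
"transcriptome": the `fig1e` pair sets the reference-gene abundance such
that the summed count/length rate is equal in both samples (rate budget
0.013), encoding the standard assumption that the remainder of the
transcriptome is constant in TPM terms and making the expected TPM fold
equal the molar fold. Second, the `fig1e`/`fig1f` presets use
`polya_capture_rate` = 0.15 (a 3′-coverage-enriched protocol) so that the
poly(A)-read-based estimates carry adequate counting statistics at the
benchmark depth of 100,000 reads; the error budget was sized from binomial
standard deviations (≈500–700 proximal tail reads in the limiting samples,
i.e. ≈4% relative noise on the limiting fraction) ahead of time.

### Determinism and scale

All randomness flows through one `numpy` generator per operation, seeded
explicitly; identical (spec, preset, seed) triples produce byte-identical
FASTA/GFF3/SAM/FASTQ/truth outputs, and `run-all` writes a log with every
parameter, tally and output checksum. The test suite runs the full pipeline
at depths of 1,200–8,000 reads for structural checks and 50,000–100,000
reads for recovery checks (a 100,000-read sample simulates and analyzes in a
few seconds); the acceptance script uses 100,000 reads per sample, the depth
at which the calibrated quantities are recovered within a few percent.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive internally (the native convention of
  GFF3 and SAM POS, and the one the data types here are specified in); BED
  output is 0-based half-open, converted in exactly one tested helper pair.
  This deliberately trades the half-open arithmetic convenience for having
  no convention change anywhere inside the pipeline.
* `rpm` rejects a zero denominator; `tpm` of an all-zero count vector is
  all-zero (logged), not an error; `isoform_abundance` with zero poly(A)
  reads returns missing values (logged).
* Ratio estimates of the form D/P are slightly biased upward at finite
  counts (Jensen's inequality, ≈ ratio × Var(P)/E[P]²; about +3% at 600
  proximal reads); benchmark tolerances absorb this rather than correcting
  for it.
* Empty event lists cluster to an empty list; an empty GFF3 (header only)
  loads as an empty model set; `n_reads = 0` simulates valid empty outputs,
  while an all-zero abundance vector is rejected.

## Known limitations

* The tail caller requires the clip to be strictly terminal and does not
  estimate tail lengths; long-read/direct-RNA tail calling is out of scope.
* Cluster counts are hard assignments; there is no probabilistic peak model
  or deconvolution of overlapping clusters.
* Gene quantification is union-count based, not an EM over isoforms; it is
  exact under the simulator's sampling model but approximate on real data.
* The DE stand-in (Welch *t* + BH) has no dispersion shrinkage and is not
  appropriate for real low-replicate count data; it exists to drive the
  flagging/ranking contracts.
* Antisense quantification is supported only insofar as the library is
  stranded; no antisense features are annotated in the synthetic genome.
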