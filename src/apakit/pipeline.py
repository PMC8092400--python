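"""End-to-end orchestration: configuration, the analysis pipeline and run-all.

The pipeline over a set of samples is:

1. build (or load) the genome FASTA and GFF3 annotation;
2. simulate reads per sample from presets (or take provided alignments);
3. scan alignments for untemplated poly(A) tails;
4. discard internal-priming events against the genome;
5. pool the surviving cleavage events from *all* samples into one shared
   cluster set, then count per sample (so stages/genotypes are compared on
   the same clusters);
6. classify clusters as proximal/distal/intergenic against the gene models;
7. quantify per sample (gene TPM, cluster RPM, ratio, isoform abundance);
8. assemble the stage-series long table and run the configured comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import quantify
from .clusters import (
    CleavageEvent,
    IPFilterParams,
    build_clusters,
    classify_clusters,
    clusters_to_bed_rows,
    cluster_id,
)
from .compare import compare_groups
from .gffio import load_gff3, write_bed6
from .simulate import GenomeSpec, StagePreset, build_genome, default_genome_spec, get_preset, simulate_reads
from .tails import TailParams, scan_alignments, write_tailcalls_tsv

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    tail: TailParams = field(default_factory=TailParams)
    ip: IPFilterParams = field(default_factory=IPFilterParams)
    merge_dist: int = 25
    terminator_window: int = 100
    pseudocount_reads: float = 1.0

    def validate(self) -> None:
        if self.merge_dist < 0 or self.terminator_window < 0:
            raise ValueError("distances must be >= 0")
        if self.pseudocount_reads < 0:
            raise ValueError("pseudocount_reads must be >= 0")


@dataclass
class SampleConfig:
    name: str
    preset: str | None = None
    bam: str | None = None
    seed: int | None = None
    n_reads: int | None = None
    stage: str = ""
    genotype: str = ""
    replicate: int = 1

    def validate(self) -> None:
        if (self.preset is None) == (self.bam is None):
            raise ValueError(f"sample {self.name}: exactly one of preset/bam required")
        if self.bam is not None and not Path(self.bam).exists():
            raise ValueError(f"sample {self.name}: alignment file {self.bam} not found")
        if self.preset is not None:
            get_preset(self.preset)


@dataclass
class PipelineConfig:
    out_dir: str
    samples: list[SampleConfig]
    genome_fasta: str | None = None
    gff3: str | None = None
    genome_seed: int = 7
    params: PipelineParams = field(default_factory=PipelineParams)
    comparisons: list[dict] = field(default_factory=list)
    stage_order: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        p = d.get("params", {})
        tail = TailParams(
            min_clip_len=p.get("min_clip_len", 4),
            min_purity=p.get("min_purity", 0.8),
        )
        ip = IPFilterParams(
            window_len=p.get("window_len", 10),
            max_a_fraction=p.get("max_a_fraction", 0.7),
            max_a_run=p.get("max_a_run", 6),
        )
        params = PipelineParams(
            tail=tail,
            ip=ip,
            merge_dist=p.get("merge_dist", 25),
            terminator_window=p.get("terminator_window", 100),
            pseudocount_reads=p.get("pseudocount", 1.0),
        )
        samples = [SampleConfig(**s) for s in d["samples"]]
        return cls(
            out_dir=d["out_dir"],
            samples=samples,
            genome_fasta=d.get("genome_fasta"),
            gff3=d.get("gff3"),
            genome_seed=d.get("genome_seed", 7),
            params=params,
            comparisons=d.get("comparisons", []),
            stage_order=d.get("stage_order", []),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        self.params.validate()
        if not self.samples:
            raise ValueError("no samples configured")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names")
        for s in self.samples:
            s.validate()
        for path in (self.genome_fasta, self.gff3):
            if path is not None and not Path(path).exists():
                raise ValueError(f"configured path {path} not found")
        known = set(names)
        for comp in self.comparisons:
            for key in ("group_a", "group_b"):
                missing = set(comp.get(key, [])) - known
                if missing:
                    raise ValueError(f"comparison {comp.get('name')}: unknown samples {sorted(missing)}")


@dataclass
class AnalysisResult:
    clusters: list
    quants: dict  # sample -> SampleQuant
    tallies: dict  # sample -> dict
    series: object = None  # stage-series DataFrame
    comparisons: dict = field(default_factory=dict)
    genome_fasta: Path | None = None
    gff3: Path | None = None
    sam_paths: dict = field(default_factory=dict)
    truths: dict = field(default_factory=dict)


def analyze_samples(
    sample_sams: dict[str, Path],
    genome_fasta,
    gff3,
    params: PipelineParams | None = None,
) -> AnalysisResult:
    """Run stages 3-7 on existing alignments (the pipeline's core)."""
    from pyfaidx import Fasta

    params = params or PipelineParams()
    fasta = Fasta(str(genome_fasta))
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    genes = load_gff3(gff3)

    events: list[CleavageEvent] = []
    tallies: dict[str, dict] = {}
    for sample, sam in sample_sams.items():
        calls, tally = scan_alignments(sam, params.tail)
        tallies[sample] = tally.as_dict()
        kept = 0
        for c in calls:
            from .clusters import internal_priming_check

            if internal_priming_check(genome, c.chrom, c.strand, c.cleavage_pos, params.ip):
                events.append(CleavageEvent(c.chrom, c.strand, c.cleavage_pos, sample))
                kept += 1
        tallies[sample]["ip_filtered"] = tally.accepted - kept
        log.info("%s: %d tail calls, %d after internal-priming filter", sample, tally.accepted, kept)

    clusters = classify_clusters(
        build_clusters(events, params.merge_dist), genes, params.terminator_window
    )
    quants = {
        sample: quantify.quantify_sample(
            sample, sam, clusters, genes, params.pseudocount_reads
        )
        for sample, sam in sample_sams.items()
    }
    return AnalysisResult(
        clusters=clusters,
        quants=quants,
        tallies=tallies,
        genome_fasta=Path(str(genome_fasta)),
        gff3=Path(str(gff3)),
        sam_paths=dict(sample_sams),
    )


def simulate_and_analyze(
    samples: list[tuple[str, str | StagePreset, int, int | None]],
    workdir,
    genome_spec: GenomeSpec | None = None,
    genome_seed: int = 7,
    params: PipelineParams | None = None,
) -> AnalysisResult:
    """Convenience: build the default genome, simulate each
    (name, preset, seed, n_reads) sample and run the core pipeline."""
    workdir = Path(workdir)
    fasta, gff3 = build_genome(genome_spec or default_genome_spec(), genome_seed, workdir)
    sams: dict[str, Path] = {}
    truths = {}
    for name, preset, seed, n_reads in samples:
        if isinstance(preset, str):
            preset = get_preset(preset)
        if n_reads is not None:
            preset = preset.replace(n_reads=n_reads)
        sim = simulate_reads(fasta, gff3, preset, workdir / "sim", seed=seed, sample_name=name)
        sams[name] = sim.sam_path
        truths[name] = sim.truth
    result = analyze_samples(sams, fasta, gff3, params)
    result.truths = truths
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, seed: int | None = None) -> AnalysisResult:
    """Validate, run every stage and write all outputs under out_dir.

    Deterministic given (config, seed). The run log records parameters,
    per-sample tallies and a checksum of every output file. On failure the
    partial outputs are removed (the log is kept) and the error re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log_path = out / "run_log.json"
    run_log: dict = {
        "params": {
            "tail": config.params.tail.__dict__,
            "ip": config.params.ip.__dict__,
            "merge_dist": config.params.merge_dist,
            "terminator_window": config.params.terminator_window,
            "pseudocount_reads": config.params.pseudocount_reads,
            "genome_seed": config.genome_seed,
            "seed": seed,
        },
        "samples": {},
        "outputs": {},
    }

    def track(path: Path) -> Path:
        created.append(path)
        return path

    try:
        if config.genome_fasta and config.gff3:
            fasta, gff3 = Path(config.genome_fasta), Path(config.gff3)
        else:
            fasta, gff3 = build_genome(default_genome_spec(), config.genome_seed, out)
            track(fasta), track(gff3)

        sams: dict[str, Path] = {}
        for i, s in enumerate(config.samples):
            if s.bam:
                sams[s.name] = Path(s.bam)
            else:
                preset = get_preset(s.preset)
                if s.n_reads is not None:
                    preset = preset.replace(n_reads=s.n_reads)
                sample_seed = s.seed if s.seed is not None else (seed or 0) * 1000 + i
                sim = simulate_reads(
                    fasta, gff3, preset, out / "sim", seed=sample_seed, sample_name=s.name
                )
                for p in (sim.sam_path, sim.fastq_path, sim.truth_path):
                    track(p)
                sams[s.name] = sim.sam_path
                run_log["samples"][s.name] = {"preset": s.preset, "seed": sample_seed}

        result = analyze_samples(sams, fasta, gff3, config.params)
        run_log["tallies"] = result.tallies

        tails_dir = out / "tails"
        tails_dir.mkdir(exist_ok=True)
        for sample, sam in sams.items():
            calls, _ = scan_alignments(sam, config.params.tail)
            write_tailcalls_tsv(calls, track(tails_dir / f"{sample}.tails.tsv"))

        write_bed6(track(out / "clusters.bed"), clusters_to_bed_rows(result.clusters))
        counts_path = track(out / "cluster_counts.tsv")
        with open(counts_path, "w") as fh:
            names = list(sams)
            fh.write("cluster_id\tgene_id\tclass\tsummit\t" + "\t".join(names) + "\n")
            for c in result.clusters:
                row = "\t".join(str(c.sample_counts.get(n, 0)) for n in names)
                fh.write(f"{cluster_id(c)}\t{c.gene_id or ''}\t{c.cluster_class}\t{c.summit}\t{row}\n")

        quant_dir = out / "quant"
        quant_dir.mkdir(exist_ok=True)
        for sample, q in result.quants.items():
            q.gene_table.to_csv(track(quant_dir / f"{sample}.genes.tsv"), sep="\t", index=False)
            q.cluster_table.to_csv(track(quant_dir / f"{sample}.clusters.tsv"), sep="\t", index=False)
            q.gene_apa.to_csv(track(quant_dir / f"{sample}.apa.tsv"), sep="\t", index=False)

        by_name = {s.name: s for s in config.samples}
        entries = [
            (by_name[n].stage or "all", by_name[n].replicate, q)
            for n, q in result.quants.items()
        ]
        result.series = quantify.stage_series(entries, config.stage_order or None)
        result.series.to_csv(track(out / "stage_series.tsv"), sep="\t", index=False)

        for comp in config.comparisons:
            qa = [result.quants[n] for n in comp["group_a"]]
            qb = [result.quants[n] for n in comp["group_b"]]
            table = compare_groups(qa, qb)
            name = comp.get("name", "comparison")
            result.comparisons[name] = table
            table.to_csv(track(out / f"compare_{name}.tsv"), sep="\t", index=False)

        for p in created:
            run_log["outputs"][str(p.relative_to(out))] = _sha256(p)
        with open(log_path, "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
        return result
    except Exception:
        with open(log_path, "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
        for p in created:
            if p.exists():
                p.unlink()
        raise
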