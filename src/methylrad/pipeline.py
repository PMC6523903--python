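"""End-to-end orchestration: simulate -> demultiplex -> catalog -> test ->
annotate, from a single validated configuration with one master seed.

Each stage writes plain-text outputs into the run directory so that every
stage is independently re-runnable and diffable; the resolved configuration
is echoed into the run directory.  Random streams are namespaced per
module from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import catalog as cat
from . import demux as dmx
from . import stats as st
from .digest import ReadSet, digest as _digest, select_library_fragments, simulate_reads
from .enzymes import CONTEXT_ENZYME, DEFAULT_REGISTRY
from .genome import Genome, generate_genome
from .synthetic import (
    DEFAULT_BASELINE_RATES,
    Methylome,
    StudyDesign,
    TruthTable,
    evaluate_recovery,
    plant_methylome,
    random_gene_models,
)

#: 7-bp sample barcodes (pairwise Hamming distance >= 3)
DEFAULT_BARCODES = (
    "AACCTTG", "CCGGAAT", "GGTTCCA", "TTAAGGC", "ACGTACG", "CATGCTA",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | analyze
    seed: int = 0
    replicates: int = 3
    contexts: tuple[str, ...] = ("CG", "CHH", "CHG")
    # synthetic genome; the default scale yields >= 2000 selectable loci
    # across the three libraries (the sparsest cutter limits locus density)
    n_chrom: int = 2
    chrom_length: int = 7_000_000
    gc_fraction: float = 0.4
    n_genes: int = 120
    # methylome
    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    n_dml_per_context: int = 200
    effect: float = 1.0
    # library chemistry
    min_fragment: int = 300
    max_fragment: int = 500
    depth: float = 20.0
    read_len: int = 150
    error_rate: float = 0.001
    # demultiplexing / QC
    max_barcode_mismatch: int = 0
    require_remnant: bool = True
    quality_window: int = 10
    quality_threshold: float = 20.0
    min_read_len: int = 40
    adapter: str = ""
    # catalog
    identity_threshold: float = 0.90
    min_locus_count: int = 3
    # statistics
    prefilter_fdr: float = 0.05
    alpha: float = 0.01
    test_method: str = "fisher"
    aggregate: str = "sum"
    dispersion: float = 0.0
    # annotation
    window: int = 2000
    # analyze-mode inputs
    fastq: dict = field(default_factory=dict)  # context -> fastq path
    sample_sheet: str = ""
    genome_fasta: str = ""
    gff3: str = ""

    def __post_init__(self) -> None:
        self.contexts = tuple(self.contexts)
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        for ctx in self.contexts:
            if ctx not in CONTEXT_ENZYME:
                raise ConfigError(f"unknown context {ctx!r}")
        if self.min_fragment > self.max_fragment:
            raise ConfigError("min_fragment exceeds max_fragment")
        if not 0 < self.identity_threshold <= 1:
            raise ConfigError("identity_threshold must be in (0, 1]")
        if self.mode == "analyze":
            for name, path in (("sample_sheet", self.sample_sheet),
                               ("genome_fasta", self.genome_fasta)):
                if not path:
                    raise ConfigError(f"analyze mode requires {name}")
                if not Path(path).exists():
                    raise ConfigError(f"{name} not found: {path}")
            if not self.fastq:
                raise ConfigError("analyze mode requires fastq inputs")
            for ctx, path in self.fastq.items():
                if not Path(path).exists():
                    raise ConfigError(f"fastq for {ctx} not found: {path}")

    def design(self) -> StudyDesign:
        return StudyDesign(self.replicates, self.contexts, self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["contexts"] = list(self.contexts)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def make_sample_sheet(design: StudyDesign, registry=DEFAULT_REGISTRY) -> dmx.SampleSheet:
    rows = []
    for context in design.contexts:
        remnant = registry.get_enzyme(CONTEXT_ENZYME[context]).remnant
        for i, sample in enumerate(design.samples):
            rows.append(
                dmx.SampleSheetRow(
                    sample, design.group_of(sample), context, DEFAULT_BARCODES[i], remnant
                )
            )
    return dmx.SampleSheet(rows)


def simulate_library(
    genome: Genome,
    methylome: Methylome,
    design: StudyDesign,
    context: str,
    cfg: RunConfig,
    rng: np.random.Generator,
    registry=DEFAULT_REGISTRY,
) -> list[ReadSet]:
    """Digest every sample, size-select, and simulate pooled reads."""
    enzyme = registry.get_enzyme(CONTEXT_ENZYME[context])
    readsets = []
    for i, sample in enumerate(design.samples):
        frags = _digest(genome, methylome.getter(sample), enzyme, "MseI", rng, registry)
        selected = select_library_fragments(frags, cfg.min_fragment, cfg.max_fragment)
        readsets.append(
            simulate_reads(
                genome,
                selected,
                cfg.depth,
                DEFAULT_BARCODES[i],
                cfg.read_len,
                cfg.error_rate,
                rng,
                sample=sample,
            )
        )
    return readsets


def write_pooled_fastq(readsets: list[ReadSet], path: Path, rng) -> int:
    """Pool samples into one library FASTQ (deterministic interleaved order)."""
    n = 0
    with open(path, "w") as fh:
        for rs in readsets:
            rs.write_fastq(fh)
            n += len(rs)
    return n


def read_fastq(path: Path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title, seq, qual


def _qc_reads(reads, cfg: RunConfig):
    kept, dropped = [], 0
    for rid, seq, qual in reads:
        if cfg.adapter:
            seq, qual = dmx.adapter_trim(seq, qual, cfg.adapter)
        trimmed = dmx.quality_trim(
            seq, qual, cfg.quality_window, cfg.quality_threshold, cfg.min_read_len
        )
        if trimmed is None:
            dropped += 1
            continue
        kept.append((rid, trimmed[0], trimmed[1]))
    return kept, dropped


def _called_site_positions(
    annotated: pd.DataFrame, context: str, registry=DEFAULT_REGISTRY
) -> list[tuple[str, int, str]]:
    """Map placed DML back to the blocking cytosine of their sensitive site."""
    from .synthetic import _plus_blocking_position

    enzyme = registry.get_enzyme(CONTEXT_ENZYME[context])
    out = []
    for _, row in annotated.iterrows():
        if row["placement"] not in ("unique", "rescued"):
            continue
        if row["strand"] == "+":
            cut, orient = int(row["start"]), "+"
        else:
            cut = int(row["end"])
            orient = "+" if enzyme.palindromic else "-"
        site_start = enzyme.site_start_from_cut(cut, orient)
        try:
            pos = _plus_blocking_position(enzyme, site_start, orient)
        except ValueError:
            continue
        out.append((row["chrom"], pos, row["direction"]))
    return out


def run_pipeline(cfg: RunConfig, outdir: str | Path, registry=DEFAULT_REGISTRY) -> dict:
    """Execute all stages; returns (and writes) the run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.validate()
    cfg.to_yaml(outdir / "config.yaml")
    design = cfg.design()
    streams = _streams(
        cfg.seed, ["genome", "genes", "methylome", "gene2go"] + [f"library:{c}" for c in cfg.contexts]
    )

    truth = None
    if cfg.mode == "simulate":
        genome = generate_genome(
            streams["genome"], cfg.n_chrom, cfg.chrom_length, cfg.gc_fraction
        )
        genome.to_fasta(outdir / "genome.fa")
        genes = random_gene_models(genome, cfg.n_genes, streams["genes"])
        ann.write_gff3(genes, outdir / "genes.gff3")
        methylome, truth = plant_methylome(
            genome,
            design,
            cfg.baseline_rates,
            cfg.n_dml_per_context,
            cfg.effect,
            streams["methylome"],
            cfg.min_fragment,
            cfg.max_fragment,
            registry=registry,
        )
        truth.to_tsv(outdir / "truth.tsv")
        methylome.to_tsv(outdir / "methylome.tsv")
        sheet = make_sample_sheet(design, registry)
        sheet.to_tsv(outdir / "sample_sheet.tsv")
    else:
        genome = Genome.from_fasta(cfg.genome_fasta)
        genes = ann.read_gff3(cfg.gff3) if cfg.gff3 else []
        sheet = dmx.SampleSheet.from_tsv(cfg.sample_sheet)

    summary: dict = {"mode": cfg.mode, "seed": cfg.seed, "contexts": {}}
    all_dml = []
    all_annotated = []
    called_positions = []

    for context in cfg.contexts:
        ctx_dir = outdir / context
        ctx_dir.mkdir(exist_ok=True)
        if cfg.mode == "simulate":
            readsets = simulate_library(
                genome, methylome, design, context, cfg, streams[f"library:{context}"], registry
            )
            write_pooled_fastq(readsets, ctx_dir / "reads.fastq", None)
            pooled = read_fastq(ctx_dir / "reads.fastq")
        else:
            pooled = read_fastq(Path(cfg.fastq[context]))

        assigned, report = dmx.demultiplex(
            pooled, sheet.library(context), cfg.max_barcode_mismatch, cfg.require_remnant
        )
        report.to_csv(ctx_dir / "demux_report.tsv", sep="\t", index=False)
        totals = dmx.demux_totals(report)

        qc_counts = {}
        reads_by_sample: dict[str, list[str]] = {}
        for sample, reads in assigned.items():
            kept, dropped = _qc_reads(reads, cfg)
            qc_counts[sample] = {"kept": len(kept), "discarded": dropped}
            reads_by_sample[sample] = [seq for _, seq, _ in kept]

        pooled_reads = [s for sample in design.samples for s in reads_by_sample.get(sample, [])]
        catalog = cat.cluster_reads(pooled_reads, cfg.identity_threshold)
        catalog.to_fasta(ctx_dir / "catalog.fa")
        matrix = cat.assign_and_count(catalog, reads_by_sample)
        matrix = cat.drop_low_support(matrix, cfg.min_locus_count)
        matrix.to_tsv(ctx_dir / "counts.tsv")

        norm = st.cpm_normalize(matrix.counts, matrix.library_sizes, design)
        retained = st.prefilter_loci(norm, design, cfg.prefilter_fdr)
        pd.Series(retained).to_csv(ctx_dir / "prefiltered.txt", index=False, header=False)

        pc1_fraction = None
        if len(retained) >= 2:
            scores, fractions = st.pca_scores(norm.cpm.loc[retained])
            scores.to_csv(ctx_dir / "pca_scores.tsv", sep="\t")
            pd.Series(fractions, name="explained").to_csv(
                ctx_dir / "pca_variance.tsv", sep="\t", index_label="component"
            )
            pc1_fraction = float(fractions[0])
            Z, _ = st.average_linkage_cluster(norm.cpm.loc[retained].T)
            (ctx_dir / "samples_dendrogram.nwk").write_text(
                st.linkage_to_newick(Z, list(norm.cpm.columns))
            )

        # exact test over every catalog locus (calibration diagnostics),
        # DML = prefiltered loci below alpha
        full_table = st.exact_test_table(
            matrix, design, cfg.test_method, cfg.aggregate, cfg.dispersion
        )
        full_table.to_csv(ctx_dir / "exact_test_all_loci.tsv", sep="\t")
        dml = full_table.loc[full_table.index.isin(retained) & (full_table["p"] < cfg.alpha)].copy()
        dml["context"] = context
        dml.to_csv(ctx_dir / "dml.tsv", sep="\t")

        consensus = dict(zip(catalog.locus_ids, catalog.consensus))
        annotated = ann.annotate_dml(dml, consensus, genome, genes, cfg.window)
        annotated.to_csv(ctx_dir / "dml_annotated.tsv", sep="\t")
        ann.dml_to_bed(annotated, ctx_dir / "dml.bed")

        if cfg.mode == "simulate":
            called_positions += _called_site_positions(annotated, context, registry)

        all_dml.append(dml)
        all_annotated.append(annotated)
        summary["contexts"][context] = {
            "reads_total": totals["total"],
            "reads_assigned": totals["assigned"],
            "reads_unassigned": totals["unassigned"],
            "n_loci": int(len(matrix.counts)),
            "n_prefiltered": int(len(retained)),
            "n_dml": int(len(dml)),
            "pc1_variance_fraction": pc1_fraction,
            "exact_p_below_alpha_all_loci": float((full_table["p"] < cfg.alpha).mean())
            if len(full_table)
            else None,
            "qc": qc_counts,
        }

    dml_all = pd.concat(all_dml) if all_dml else pd.DataFrame()
    annotated_all = pd.concat(all_annotated) if all_annotated else pd.DataFrame()
    directions = st.direction_summary(dml_all)
    directions.to_csv(outdir / "direction_summary.tsv", sep="\t", index=False)
    locations = ann.location_distribution(annotated_all) if len(annotated_all) else pd.DataFrame()
    locations.to_csv(outdir / "location_distribution.tsv", sep="\t", index=False)
    summary["n_dml_total"] = int(len(dml_all))
    summary["direction_summary"] = directions.to_dict("records")
    summary["location_distribution"] = locations.to_dict("records") if len(locations) else []

    if cfg.mode == "simulate" and truth is not None:
        recovery = evaluate_recovery(called_positions, truth)
        summary["recovery"] = recovery
        pd.DataFrame([recovery]).to_csv(outdir / "recovery.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
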