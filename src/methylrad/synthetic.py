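"""Synthetic methylomes with planted differential methylation.

The generator emulates the study design the pipeline is built for: two
phenotype groups (true-to-type and off-type), three biological replicates
each, and three context-specific libraries.  Methylation is bimodal: each
assay-relevant cytosine is either fully methylated (a site silenced in all
samples, drawn per context at the baseline rate) or unmethylated.
Differential loci are planted only at cytosines the assay can see -- the
blocking cytosine of a sensitive-enzyme site that terminates a size-
selectable library fragment -- because methylation anywhere else never
changes read counts.

Directions follow the assay's inversion: ``hypo_in_TT`` means the
true-to-type group is LESS methylated there (so it yields MORE reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import digest, select_library_fragments, sensitive_cut_index
from .enzymes import CONTEXT_ENZYME, DEFAULT_REGISTRY
from .genome import Genome, classify_context

GROUPS = ("true_to_type", "off_type")
DIRECTIONS = ("hypo_in_TT", "hyper_in_TT")

#: baseline probability that an assay-relevant site is (fully) methylated.
#: CG methylation dominates in plant genomes, CHH is sparse; these are free
#: parameters of the generator, not estimates for any real genome.
DEFAULT_BASELINE_RATES = {"CG": 0.3, "CHG": 0.15, "CHH": 0.05}


@dataclass(frozen=True)
class StudyDesign:
    """3 + 3 replicate design over two phenotype groups."""

    replicates: int = 3
    contexts: tuple[str, ...] = ("CG", "CHH", "CHG")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")

    @property
    def groups(self) -> tuple[str, str]:
        return GROUPS

    @property
    def samples(self) -> list[str]:
        return [f"TT{i + 1}" for i in range(self.replicates)] + [
            f"OT{i + 1}" for i in range(self.replicates)
        ]

    def group_of(self, sample: str) -> str:
        return "true_to_type" if sample.startswith("TT") else "off_type"

    def samples_of(self, group: str) -> list[str]:
        prefix = "TT" if group == "true_to_type" else "OT"
        return [s for s in self.samples if s.startswith(prefix)]


class Methylome:
    """Sparse per-sample methylation levels; unlisted cytosines are 0."""

    def __init__(self, samples: list[str]):
        self.samples = list(samples)
        self.levels: dict[str, dict[tuple[str, int, str], float]] = {
            s: {} for s in samples
        }

    def set_level(self, sample: str, chrom: str, pos: int, strand: str, m: float) -> None:
        if not 0.0 <= m <= 1.0:
            raise ValueError("methylation level must be in [0, 1]")
        self.levels[sample][(chrom, pos, strand)] = m

    def level(self, sample: str, chrom: str, pos: int, strand: str) -> float:
        return self.levels[sample].get((chrom, pos, strand), 0.0)

    def getter(self, sample: str):
        """(chrom, pos, strand) -> level callable for :func:`~methylrad.digest.digest`."""
        table = self.levels[sample]
        return lambda chrom, pos, strand: table.get((chrom, pos, strand), 0.0)

    def to_tsv(self, path: str | Path, genome: Genome | None = None) -> None:
        rows = []
        for sample in self.samples:
            for (chrom, pos, strand), m in sorted(self.levels[sample].items()):
                ctx = classify_context(genome, chrom, pos, strand) if genome else "."
                rows.append((chrom, pos, strand, ctx, sample, m))
        pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "sample", "level"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Methylome":
        df = pd.read_csv(path, sep="\t")
        me = cls(sorted(df["sample"].unique()))
        for row in df.itertuples(index=False):
            me.set_level(row.sample, row.chrom, int(row.pos), row.strand, float(row.level))
        return me


class TruthTable:
    """Planted differential loci: the ground truth for recovery scoring."""

    COLUMNS = [
        "chrom", "pos", "context", "direction",
        "level_tt", "level_ot", "site_start", "site_strand",
    ]

    def __init__(self, df: pd.DataFrame | None = None):
        self.df = (
            df.reset_index(drop=True)
            if df is not None
            else pd.DataFrame(columns=self.COLUMNS)
        )

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"].astype(int)))

    def direction_of(self) -> dict[tuple[str, int], str]:
        return {
            (c, int(p)): d
            for c, p, d in zip(self.df["chrom"], self.df["pos"], self.df["direction"])
        }

    def to_tsv(self, path: str | Path) -> None:
        # BED6-derived: chrom, start, end, name, score, strand + extra columns
        out = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "start": self.df["pos"].astype(int),
                "end": self.df["pos"].astype(int) + 1,
                "name": self.df["context"] + ":" + self.df["direction"],
                "score": 0,
                "strand": "+",
                "level_tt": self.df["level_tt"],
                "level_ot": self.df["level_ot"],
                "site_start": self.df["site_start"].astype(int),
                "site_strand": self.df["site_strand"],
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        raw = pd.read_csv(path, sep="\t")
        name = raw["name"].str.split(":", expand=True)
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["start"].astype(int),
                "context": name[0],
                "direction": name[1],
                "level_tt": raw["level_tt"],
                "level_ot": raw["level_ot"],
                "site_start": raw["site_start"].astype(int),
                "site_strand": raw["site_strand"],
            }
        )
        return cls(df)


def assayable_sites(
    genome: Genome,
    context: str,
    min_len: int = 300,
    max_len: int = 500,
    registry=DEFAULT_REGISTRY,
    methylation=None,
) -> list[tuple[str, int, str]]:
    """Sensitive-site matches that terminate a selectable library fragment.

    Returns (chrom, site_start, match_strand) for every site whose cut, under
    the given (deterministic 0/1) methylome, borders a size-selected
    sensitive+MseI fragment.  These are the loci the assay can observe.
    """
    enzyme = registry.get_enzyme(CONTEXT_ENZYME[context])
    frags = digest(genome, methylation, enzyme, "MseI", rng=0, registry=registry)
    selected = select_library_fragments(frags, min_len, max_len)
    out = []
    seen = set()
    for chrom in genome.sequences:
        index = sensitive_cut_index(genome, chrom, enzyme)
        for f in selected:
            if f.chrom != chrom:
                continue
            cut = f.start if (f.left_end == enzyme.name and f.left_readable) else f.end
            hit = index.get(cut)
            if hit and (chrom, hit[0]) not in seen:
                seen.add((chrom, hit[0]))
                out.append((chrom, hit[0], hit[1]))
    out.sort()
    return out


def _plus_blocking_position(enzyme, site_start: int, strand: str) -> int:
    """Genomic position of the top-strand blocking cytosine of a site match."""
    for pos, s in enzyme.blocking_at(site_start, strand):
        if s == "+":
            return pos
    raise ValueError(f"{enzyme.name} has no top-strand blocking cytosine")


def plant_methylome(
    genome: Genome,
    design: StudyDesign,
    baseline_rates: dict[str, float] | None = None,
    n_dml_per_context: int = 200,
    effect: float = 1.0,
    rng: np.random.Generator | int | None = None,
    min_len: int = 300,
    max_len: int = 500,
    min_spacing: int = 1000,
    registry=DEFAULT_REGISTRY,
) -> tuple[Methylome, TruthTable]:
    """Baseline methylation plus planted DML, shared truth recorded.

    Baseline: every sensitive-site blocking cytosine is fully methylated with
    the context's baseline probability, identically in all samples (so group
    means are equal at non-DML sites).  DML: ``n_dml_per_context`` assayable,
    baseline-unmethylated sites per context, split ~evenly between
    ``hypo_in_TT`` (m=0 in TT, m=effect in OT) and ``hyper_in_TT``
    (m=effect in TT, m=0 in OT), spaced >= ``min_spacing`` apart so planted
    loci do not interact through fragment structure.
    """
    if baseline_rates is None:
        baseline_rates = dict(DEFAULT_BASELINE_RATES)
    if not 0.0 < effect <= 1.0:
        raise ValueError("effect must be in (0, 1]")
    for ctx, rate in baseline_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"baseline rate for {ctx} outside [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    methylome = Methylome(design.samples)
    truth_rows = []
    planted_positions: set[tuple[str, int]] = set()
    for context in design.contexts:
        enzyme = registry.get_enzyme(CONTEXT_ENZYME[context])
        rate = baseline_rates.get(context, 0.0)

        # shared baseline: site either silenced everywhere (m=1) or open
        baseline: dict[tuple[str, int, str], float] = {}
        for chrom in genome.sequences:
            matches = genome.sites(enzyme, chrom)
            methylated = rng.random(len(matches)) < rate
            for (start, strand), is_met in zip(matches, methylated):
                if is_met:
                    pos = _plus_blocking_position(enzyme, start, strand)
                    baseline[(chrom, pos, "+")] = 1.0
        for sample in design.samples:
            methylome.levels[sample].update(baseline)

        if n_dml_per_context == 0:
            continue
        base_getter = lambda chrom, pos, strand: baseline.get((chrom, pos, strand), 0.0)
        candidates = [
            (chrom, start, strand)
            for chrom, start, strand in assayable_sites(
                genome, context, min_len, max_len, registry, base_getter
            )
        ]
        # enforce spacing between planted sites (deterministic greedy pick
        # over a random permutation of candidates)
        order = rng.permutation(len(candidates))
        chosen: list[tuple[str, int, str]] = []
        taken: dict[str, list[int]] = {}
        for idx in order:
            chrom, start, strand = candidates[idx]
            near = [p for p in taken.get(chrom, []) if abs(p - start) < min_spacing]
            if near:
                continue
            # overlapping recognition sites of different enzymes can share a
            # cytosine; never plant the same position for two contexts
            if (chrom, _plus_blocking_position(enzyme, start, strand)) in planted_positions:
                continue
            chosen.append((chrom, start, strand))
            taken.setdefault(chrom, []).append(start)
            if len(chosen) == n_dml_per_context:
                break
        if len(chosen) < n_dml_per_context:
            raise ValueError(
                f"context {context}: requested {n_dml_per_context} DML but only "
                f"{len(chosen)} assayable, unmethylated, spaced sites available "
                f"({len(candidates)} before spacing)"
            )
        for i, (chrom, start, strand) in enumerate(chosen):
            direction = DIRECTIONS[i % 2]  # ~even hypo/hyper split
            pos = _plus_blocking_position(enzyme, start, strand)
            planted_positions.add((chrom, pos))
            level_tt = 0.0 if direction == "hypo_in_TT" else effect
            level_ot = effect if direction == "hypo_in_TT" else 0.0
            for sample in design.samples:
                level = level_tt if design.group_of(sample) == "true_to_type" else level_ot
                methylome.set_level(sample, chrom, pos, "+", level)
            truth_rows.append(
                (chrom, pos, context, direction, level_tt, level_ot, start, strand)
            )
    truth = TruthTable(pd.DataFrame(truth_rows, columns=TruthTable.COLUMNS))
    return methylome, truth


def evaluate_recovery(
    called: list[tuple],
    truth: TruthTable,
) -> dict[str, float]:
    """Sensitivity, empirical FDR and direction accuracy of called DML.

    ``called`` entries are (chrom, pos) or (chrom, pos, direction); positions
    refer to the planted blocking cytosine.  Direction accuracy is computed
    over true positives that carry a direction (1.0 when none do).
    """
    truth_pos = truth.positions()
    truth_dir = truth.direction_of()
    called_pos = {(c[0], int(c[1])) for c in called}
    tp = called_pos & truth_pos
    sensitivity = len(tp) / len(truth_pos) if truth_pos else 0.0
    fdr = len(called_pos - truth_pos) / max(1, len(called_pos))
    n_dir = n_dir_ok = 0
    for c in called:
        key = (c[0], int(c[1]))
        if key in truth_pos and len(c) > 2 and c[2] is not None:
            n_dir += 1
            n_dir_ok += int(c[2] == truth_dir[key])
    return {
        "sensitivity": sensitivity,
        "empirical_FDR": fdr,
        "direction_accuracy": (n_dir_ok / n_dir) if n_dir else 1.0,
        "n_called": len(called_pos),
        "n_truth": len(truth_pos),
        "n_true_positive": len(tp),
    }


def random_gene_models(
    genome: Genome,
    n_genes: int,
    rng: np.random.Generator | int | None = None,
    cds_length: tuple[int, int] = (600, 3000),
):
    """Non-overlapping single-CDS gene models scattered over the genome.

    Synthetic stand-ins for a real annotation, used to exercise the
    upstream/intragenic/downstream classifier on simulated data.
    """
    from .annotate import GeneModel

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chroms = list(genome.sequences)
    lengths = genome.lengths
    genes = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 50:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        glen = int(rng.integers(cds_length[0], cds_length[1] + 1))
        if lengths[chrom] <= glen + 4001:
            continue
        start = int(rng.integers(2000, lengths[chrom] - glen - 2001))
        # keep a 2 kb margin so upstream/downstream windows do not overlap
        if any(start - 2000 < e and start + glen + 2000 > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + glen))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{len(genes) + 1:04d}"
        genes.append(GeneModel(gid, chrom, strand, [(start, start + glen)]))
    if len(genes) < n_genes:
        raise ValueError(f"could only place {len(genes)} of {n_genes} genes")
    genes.sort(key=lambda g: (g.chrom, g.cds[0][0]))
    return genes
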