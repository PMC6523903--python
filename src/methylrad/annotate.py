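"""Placement of locus consensus sequences on the genome and classification
against gene models.

Categories (exclusive, precedence intragenic > upstream > downstream >
intergenic): *intragenic* loci overlap a CDS interval, *upstream* loci fall
in the 2000 bp window before the translational start (strand-aware: for a
minus-strand gene the window lies at higher coordinates), *downstream* in
the 2000 bp window past the translational stop.  Coordinates are 0-based
half-open internally; GFF3 I/O converts to and from 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enzymes import revcomp
from .genome import Genome
from .stats import benjamini_hochberg

CATEGORIES = ("upstream", "intragenic", "downstream", "intergenic")
DEFAULT_WINDOW = 2000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based half-open

    def __init__(self, gene_id, chrom, strand, cds):
        cds = tuple(sorted((int(a), int(b)) for a, b in cds))
        for (a, b), (c, d) in zip(cds, cds[1:]):
            if b > c:
                raise ValueError(f"{gene_id}: overlapping CDS intervals")
        if any(a >= b for a, b in cds):
            raise ValueError(f"{gene_id}: empty CDS interval")
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "cds", cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def translational_start(self) -> int:
        """Coordinate of the start codon's first base."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    def upstream_window(self, window: int = DEFAULT_WINDOW) -> tuple[int, int]:
        lo, hi = self.span
        if self.strand == "+":
            return max(0, lo - window), lo
        return hi, hi + window

    def downstream_window(self, window: int = DEFAULT_WINDOW) -> tuple[int, int]:
        lo, hi = self.span
        if self.strand == "+":
            return hi, hi + window
        return max(0, lo - window), lo


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{g.chrom}\tmethylrad\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tmethylrad\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i + 1};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        if not cds:
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, cds))
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


class Placement(NamedTuple):
    chrom: str | None
    start: int | None
    end: int | None
    strand: str | None
    status: str  # unique | rescued | multi | unplaced


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _one_mismatch_hits(genome: Genome, query: str) -> list[tuple[str, int, str]]:
    """Pigeonhole scan: with <= 1 mismatch one exact half must match."""
    half = len(query) // 2
    out = set()
    for qseq, strand in ((query, "+"), (revcomp(query), "-")):
        parts = [(qseq[:half], 0), (qseq[half:], half)]
        for chrom, seq in genome.sequences.items():
            for part, offset in parts:
                for hit in _find_all(seq, part):
                    start = hit - offset
                    if start < 0 or start + len(qseq) > len(seq):
                        continue
                    window = seq[start : start + len(qseq)]
                    mm = sum(a != b for a, b in zip(window, qseq))
                    if mm <= 1:
                        out.add((chrom, start, strand))
    return sorted(out)


def place_locus(consensus: str, genome: Genome) -> Placement:
    """Exact-match placement of a consensus (both strands), with a
    one-mismatch rescue scan when no exact hit exists.

    Multiple hits flag the locus multi-mapping (excluded downstream).
    """
    hits: list[tuple[str, int, str]] = []
    rc = revcomp(consensus)
    for chrom, seq in genome.sequences.items():
        hits += [(chrom, s, "+") for s in _find_all(seq, consensus)]
        hits += [(chrom, s, "-") for s in _find_all(seq, rc)]
    status = "unique"
    if not hits:
        hits = _one_mismatch_hits(genome, consensus)
        status = "rescued"
        if not hits:
            return Placement(None, None, None, None, "unplaced")
    if len(hits) > 1:
        return Placement(None, None, None, None, "multi")
    chrom, start, strand = hits[0]
    return Placement(chrom, start, start + len(consensus), strand, status)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_location(
    interval: tuple[str, int, int],
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> tuple[str, str | None]:
    """(category, gene id) for a locus interval.

    Precedence intragenic > upstream > downstream > intergenic; among
    qualifying genes the one with the largest overlap wins, ties broken by
    nearest translational start, then lowest gene id.
    """
    chrom, start, end = interval
    locus = (start, end)
    best: dict[str, list[tuple]] = {c: [] for c in CATEGORIES[:3]}
    for g in genes:
        if g.chrom != chrom:
            continue
        cds_ov = sum(_overlap(locus, c) for c in g.cds)
        if cds_ov > 0:
            best["intragenic"].append((cds_ov, g))
            continue
        up_ov = _overlap(locus, g.upstream_window(window))
        if up_ov > 0:
            best["upstream"].append((up_ov, g))
            continue
        down_ov = _overlap(locus, g.downstream_window(window))
        if down_ov > 0:
            best["downstream"].append((down_ov, g))
    for category in ("intragenic", "upstream", "downstream"):
        if best[category]:
            mid = (start + end) / 2
            chosen = sorted(
                best[category],
                key=lambda t: (
                    -t[0],
                    abs(t[1].translational_start - mid),
                    t[1].gene_id,
                ),
            )[0][1]
            return category, chosen.gene_id
    return "intergenic", None


def annotate_dml(
    dml: pd.DataFrame,
    consensus_by_locus: dict[str, str],
    genome: Genome,
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Place each DML consensus and classify it against the gene models."""
    extra = ["chrom", "start", "end", "strand", "placement", "category", "gene_id"]
    if dml.empty:
        out = dml.copy()
        for col in extra:
            out[col] = pd.Series(dtype=object)
        return out
    rows = []
    for locus in dml.index:
        pl = place_locus(consensus_by_locus[locus], genome)
        if pl.status in ("unique", "rescued"):
            category, gene = classify_location((pl.chrom, pl.start, pl.end), genes, window)
        else:
            category, gene = None, None
        rows.append(
            {
                "locus": locus,
                "chrom": pl.chrom,
                "start": pl.start,
                "end": pl.end,
                "strand": pl.strand,
                "placement": pl.status,
                "category": category,
                "gene_id": gene,
            }
        )
    out = pd.DataFrame(rows).set_index("locus")
    return dml.join(out)


def location_distribution(annotated: pd.DataFrame, by_context: bool = True) -> pd.DataFrame:
    """Per-context category fractions over placed loci (sums to 1)."""
    placed = annotated[annotated["placement"].isin(["unique", "rescued"])]
    if placed.empty:
        return pd.DataFrame(columns=["context", "category", "count", "fraction"])
    keys = ["context", "category"] if by_context and "context" in placed else ["category"]
    counts = placed.groupby(keys, observed=True).size().rename("count").reset_index()
    if "context" in counts:
        totals = counts.groupby("context")["count"].transform("sum")
    else:
        totals = counts["count"].sum()
    counts["fraction"] = counts["count"] / totals
    return counts


def dml_to_bed(annotated: pd.DataFrame, path: str | Path) -> None:
    placed = annotated[annotated["placement"].isin(["unique", "rescued"])]
    with open(path, "w") as fh:
        for locus, row in placed.iterrows():
            score = min(1000, int(round(-10 * np.log10(max(row["p"], 1e-100)))))
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{locus}\t{score}\t{row['strand']}\n"
            )


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """TSV (gene, term[, term name]) -> gene to GO-term-set map."""
    df = pd.read_csv(path, sep="\t")
    gene_col, term_col = df.columns[0], df.columns[1]
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def go_slim_tally(
    genes: Iterable[str],
    gene2go: dict[str, set[str]],
    background: Iterable[str],
    enrich: bool = True,
) -> pd.DataFrame:
    """GO term tally for input genes against a background, with optional
    hypergeometric enrichment (upper tail), BH-adjusted.

    Genes absent from the map count as unannotated (term ``unannotated``).
    """
    genes = list(dict.fromkeys(genes))
    background = list(dict.fromkeys(background))
    M = len(background)
    n = len(genes)
    term_bg: dict[str, int] = {}
    for g in background:
        for t in gene2go.get(g, {"unannotated"}):
            term_bg[t] = term_bg.get(t, 0) + 1
    term_in: dict[str, int] = {}
    for g in genes:
        for t in gene2go.get(g, {"unannotated"}):
            term_in[t] = term_in.get(t, 0) + 1
    rows = []
    for term in sorted(set(term_bg) | set(term_in)):
        k = term_in.get(term, 0)
        K = term_bg.get(term, 0)
        row = {"term": term, "count": k, "background_count": K}
        if enrich:
            row["p"] = float(sps.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(row)
    out = pd.DataFrame(rows)
    if enrich and not out.empty:
        out["q"] = benjamini_hochberg(out["p"])
    return out
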