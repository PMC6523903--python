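"""Methylation-sensitive double digestion, size selection and read simulation.

The library chemistry modelled here: genomic DNA is cut with MseI (always)
and one methylation-sensitive enzyme (only where its blocking cytosines are
unmethylated), fragments of 300-500 bp carrying one sensitive end and one
MseI end are size-selected, and 1x150 bp single-end reads are taken from the
sensitive end, prefixed with a 7-bp in-line barcode.  A cut at a sensitive
site is realized with probability prod(1 - m) over the site's blocking
cytosines, independently per sample.

A fragment end is *sequenceable* only when the read taken inward from it
begins with the enzyme's restriction remnant (the demultiplexer later
requires that remnant after the barcode).  For a blunt-modelled cut this is
orientation dependent: the downstream side of a canonical-orientation match
always reads the remnant, the upstream side only for enzymes whose site
geometry guarantees it (e.g. EcoT22I's single-base remnant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .enzymes import DEFAULT_REGISTRY, EnzymeSpec, revcomp
from .genome import Genome

READ_LEN = 150
BARCODE_LEN = 7


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int
    left_end: str  # enzyme name or "end" (chromosome terminus)
    right_end: str
    left_readable: bool
    right_readable: bool

    @property
    def length(self) -> int:
        return self.end - self.start


class _Cut(NamedTuple):
    pos: int
    enzyme: str
    sensitive: bool
    up_readable: bool  # read from the fragment upstream of the cut (revcomp)
    down_readable: bool  # read from the fragment downstream of the cut
    prob: float  # cut probability given the sample's methylation


def _site_cuts(
    genome: Genome,
    chrom: str,
    enzyme: EnzymeSpec,
    methylation=None,
) -> list[_Cut]:
    """One candidate cut per recognition-site match."""
    cuts = []
    for start, strand in genome.sites(enzyme, chrom):
        pos = enzyme.cut_position(start, strand)
        blocking = enzyme.blocking_at(start, strand)
        if strand == "+":
            up_ok, down_ok = enzyme.upstream_readable, True
        else:
            # reverse-complement orientation: the canonical pattern lies on
            # the bottom strand, so the roles of the two sides swap
            up_ok, down_ok = True, enzyme.upstream_readable
        if not enzyme.methylation_sensitive:
            prob = 1.0
        else:
            prob = 1.0
            for bpos, bstrand in blocking:
                m = methylation(chrom, bpos, bstrand) if methylation else 0.0
                prob *= 1.0 - m
        cuts.append(_Cut(pos, enzyme.name, enzyme.methylation_sensitive, up_ok, down_ok, prob))
    return cuts


def digest(
    genome: Genome,
    methylation,
    sensitive_enzyme: str | EnzymeSpec,
    mse_enzyme: str | EnzymeSpec = "MseI",
    rng: np.random.Generator | int | None = None,
    registry=DEFAULT_REGISTRY,
) -> list[Fragment]:
    """Digest every chromosome with the enzyme pair for one sample.

    ``methylation`` is a callable (chrom, pos, strand) -> level in [0, 1]
    (or None for a fully unmethylated sample).  Fragments tile each
    chromosome exactly: concatenating them reconstructs it.
    """
    if isinstance(sensitive_enzyme, str):
        sensitive_enzyme = registry.get_enzyme(sensitive_enzyme)
    if isinstance(mse_enzyme, str):
        mse_enzyme = registry.get_enzyme(mse_enzyme)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    fragments: list[Fragment] = []
    for chrom, seq in genome.sequences.items():
        candidates = _site_cuts(genome, chrom, mse_enzyme) + _site_cuts(
            genome, chrom, sensitive_enzyme, methylation
        )
        probs = np.array([c.prob for c in candidates])
        realized = rng.random(len(candidates)) < probs
        by_pos: dict[int, _Cut] = {}
        for cut, keep in zip(candidates, realized):
            if not keep or cut.pos <= 0 or cut.pos >= len(seq):
                continue
            prev = by_pos.get(cut.pos)
            if prev is None or (cut.sensitive and not prev.sensitive):
                by_pos[cut.pos] = cut
        cuts = sorted(by_pos)
        bounds = [0] + cuts + [len(seq)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            left = by_pos.get(a)
            right = by_pos.get(b)
            fragments.append(
                Fragment(
                    chrom,
                    a,
                    b,
                    left.enzyme if left else "end",
                    right.enzyme if right else "end",
                    left.down_readable if left else False,
                    right.up_readable if right else False,
                )
            )
    return fragments


def select_library_fragments(
    fragments: Iterable[Fragment],
    min_len: int = 300,
    max_len: int = 500,
    mse_name: str = "MseI",
) -> list[Fragment]:
    """Size selection plus the two-adapter asymmetry rule.

    A fragment enters the library iff its length is within [min_len, max_len]
    (inclusive), one end was produced by the sensitive enzyme with a
    sequenceable remnant, and the other end by MseI.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept = []
    for f in fragments:
        if not min_len <= f.length <= max_len:
            continue
        left_sens = f.left_end not in (mse_name, "end")
        right_sens = f.right_end not in (mse_name, "end")
        if (left_sens and f.left_readable and f.right_end == mse_name) or (
            right_sens and f.right_readable and f.left_end == mse_name
        ):
            kept.append(f)
    return kept


def sensitive_cut_index(
    genome: Genome, chrom: str, enzyme: EnzymeSpec
) -> dict[int, tuple[int, str]]:
    """Map top-strand cut coordinate -> (site start, match strand)."""
    return {
        enzyme.cut_position(start, strand): (start, strand)
        for start, strand in genome.sites(enzyme, chrom)
    }


@dataclass
class ReadSet:
    """Simulated single-end reads for one sample of one library."""

    sample: str
    barcode: str
    reads: list[tuple[str, str, str]]  # (read id, sequence, quality)

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, handle) -> None:
        for rid, seq, qual in self.reads:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def fragment_id(f: Fragment) -> str:
    return f"{f.chrom}:{f.start}-{f.end}"


def simulate_reads(
    genome: Genome,
    fragments: Iterable[Fragment],
    depth: float,
    barcode: str,
    read_len: int = READ_LEN,
    error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample: str = "sample",
    mse_name: str = "MseI",
    quality_char: str = "F",
) -> ReadSet:
    """Poisson(depth) reads per fragment, from the sensitive end.

    Read = barcode + genomic sequence starting at the sensitive-enzyme cut
    (reverse-complemented when that end is the fragment's right end),
    truncated to ``read_len - len(barcode)``.  Substitution errors are
    i.i.d. at ``error_rate``; qualities are constant Phred+33.
    The read id encodes the origin fragment (the simulation truth log).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if set(barcode) - set("ACGT") or len(barcode) != BARCODE_LEN:
        raise ValueError(f"barcode must be {BARCODE_LEN} bp over ACGT")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gen_len = read_len - len(barcode)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[tuple[str, str, str]] = []
    for f in fragments:
        frag_seq = genome[f.chrom][f.start : f.end]
        if f.left_end != mse_name and f.left_readable:
            insert = frag_seq[:gen_len]
        else:
            insert = revcomp(frag_seq)[:gen_len]
        template = barcode + insert
        n_copies = int(rng.poisson(depth))
        fid = fragment_id(f)
        for copy in range(n_copies):
            seq = template
            if error_rate > 0:
                n_err = int(rng.binomial(len(seq), error_rate))
                if n_err:
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    pos = rng.choice(len(arr), size=n_err, replace=False)
                    for p in pos:
                        choices = bases[bases != arr[p]]
                        arr[p] = rng.choice(choices)
                    seq = arr.tobytes().decode()
            rid = f"{sample}|{fid}|{copy}"
            reads.append((rid, seq, quality_char * len(seq)))
    return ReadSet(sample, barcode, reads)
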