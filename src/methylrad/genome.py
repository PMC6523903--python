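"""Random reference genomes and cytosine-context classification.

A synthetic genome stands in for a large plant reference at desk scale.
Cytosine contexts follow the plant convention: CG and CHG are symmetric,
CHH is asymmetric (H = A, C or T); the context of a cytosine is a pure
function of the two bases 3' of it on its own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enzymes import EnzymeSpec, SiteMatch, find_sites, revcomp

CONTEXTS = ("CG", "CHG", "CHH")


class NotACytosineError(ValueError):
    """Raised when a context is requested for a position that is not a cytosine."""


@dataclass
class Genome:
    """Chromosome id -> DNA string over {A, C, G, T}."""

    sequences: dict[str, str]
    _site_cache: dict[str, list[SiteMatch]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} has non-ACGT characters")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sites(self, enzyme: EnzymeSpec, chrom: str) -> list[SiteMatch]:
        """Recognition sites on a chromosome, memoized per enzyme."""
        key = f"{enzyme.name}:{enzyme.site}:{chrom}"
        if key not in self._site_cache:
            self._site_cache[key] = find_sites(self.sequences[chrom], enzyme)
        return self._site_cache[key]

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        return cls(
            {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        )


def generate_genome(
    seed: int | np.random.Generator,
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    gc_fraction: float = 0.4,
) -> Genome:
    """I.i.d. random genome with the requested GC content.

    Deterministic for a fixed seed; chromosomes are named chr1, chr2, ...
    """
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(n_chrom):
        draws = rng.choice(alphabet, size=chrom_length, p=[at, gc, gc, at])
        seqs[f"chr{i + 1}"] = draws.tobytes().decode()
    return Genome(seqs)


def classify_context(
    genome: Genome | str, chrom: str | None = None, pos: int = 0, strand: str = "+"
) -> str | None:
    """Context (CG / CHG / CHH) of the cytosine at ``pos`` on ``strand``.

    On the minus strand the reference base is G, read as the C of the
    reverse strand; the neighborhood then extends toward lower coordinates.
    Returns None when the context cannot be resolved at a sequence end.
    Raises :class:`NotACytosineError` if the position is not a cytosine.
    """
    seq = genome if isinstance(genome, str) else genome[chrom]
    n = len(seq)
    if strand == "+":
        if seq[pos] != "C":
            raise NotACytosineError(f"{chrom}:{pos}:+ holds {seq[pos]}, not C")
        b1 = seq[pos + 1] if pos + 1 < n else None
        b2 = seq[pos + 2] if pos + 2 < n else None
    elif strand == "-":
        if seq[pos] != "G":
            raise NotACytosineError(f"{chrom}:{pos}:- holds {seq[pos]}, not G (C on -)")
        b1 = revcomp(seq[pos - 1]) if pos - 1 >= 0 else None
        b2 = revcomp(seq[pos - 2]) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if b1 is None:
        return None
    if b1 == "G":
        return "CG"
    if b2 is None:
        return None
    return "CHG" if b2 == "G" else "CHH"


def context_census(genome: Genome) -> dict[str, int]:
    """Counts of scorable cytosines per context over both strands.

    Vectorized over the byte representation; cytosines whose context cannot
    be resolved at a sequence end are excluded.  CG + CHG + CHH equals the
    number of scorable cytosines.
    """
    totals = {c: 0 for c in CONTEXTS}
    for seq in genome.sequences.values():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        plus_c = arr[:-2] == ord("C")
        p1 = arr[1:-1]
        p2 = arr[2:]
        cg = plus_c & (p1 == ord("G"))
        chg = plus_c & (p1 != ord("G")) & (p2 == ord("G"))
        chh = plus_c & (p1 != ord("G")) & (p2 != ord("G"))
        totals["CG"] += int(cg.sum())
        totals["CHG"] += int(chg.sum())
        totals["CHH"] += int(chh.sum())
        minus_c = arr[2:] == ord("G")  # C on the minus strand
        m1 = arr[1:-1]  # complement is G iff top base is C
        m2 = arr[:-2]
        cg = minus_c & (m1 == ord("C"))
        chg = minus_c & (m1 != ord("C")) & (m2 == ord("C"))
        chh = minus_c & (m1 != ord("C")) & (m2 != ord("C"))
        totals["CG"] += int(cg.sum())
        totals["CHG"] += int(chg.sum())
        totals["CHH"] += int(chh.sum())
        # sequence-end cytosines whose CG status needs only one neighbor
        n = len(seq)
        if n >= 2 and seq[n - 2] == "C" and seq[n - 1] == "G":
            totals["CG"] += 1
        if n >= 2 and seq[1] == "G" and seq[0] == "C":
            totals["CG"] += 1
    return totals
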