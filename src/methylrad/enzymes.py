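"""Restriction enzymes for methylation-sensitive reduced-representation libraries.

The assay pairs the methylation-insensitive frequent cutter MseI with one
methylation-sensitive enzyme per cytosine context:

* CG  -> AciI   (CCGC; blocked by methylation of the CpG cytosine)
* CHH -> EcoT22I (ATGCAT; blocked by its CHH-context cytosine)
* CHG -> Fnu4HI (GCNGC; blocked by the internal CHG-context cytosine)

Cut positions are modelled as a single blunt offset on the top strand;
overhangs are ignored because downstream analysis only needs fragment
boundaries and the restriction remnant left at a fragment end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse-complement a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern:
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC character {ch!r} in {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def iupac_prefix_match(seq: str, pattern: str) -> bool:
    """Does ``seq`` start with a realization of ``pattern``?"""
    if len(seq) < len(pattern):
        return False
    return all(s in IUPAC[p] for s, p in zip(seq, pattern))


def _guaranteed_prefix(known: str, pattern: str) -> bool:
    # every realization of `known` starts with a realization of `pattern`
    if len(known) < len(pattern):
        return False
    return all(set(IUPAC[k]) <= set(IUPAC[p]) for k, p in zip(known, pattern))


class SiteMatch(NamedTuple):
    start: int
    strand: str  # '+' canonical orientation, '-' reverse-complement match


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site, blunt cut offset, methylation rule.

    ``blocking`` lists site-relative cytosine positions (with the strand the
    cytosine lies on) whose methylation abolishes cutting.  The cut succeeds
    with probability prod(1 - m) over those cytosines.
    """

    name: str
    site: str
    cut_offset: int
    blocking: tuple[tuple[int, str], ...] = ()
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside site")
        for pos, strand in self.blocking:
            base = self.site[pos]
            want = "C" if strand == "+" else "G"
            if want not in IUPAC[base]:
                raise ValueError(
                    f"{self.name}: blocking position {pos}{strand} does not hold a cytosine"
                )

    @property
    def palindromic(self) -> bool:
        return revcomp(self.site) == self.site

    @property
    def remnant(self) -> str:
        """Site bases left on the downstream fragment after the cut."""
        return self.site[self.cut_offset:]

    @property
    def upstream_readable(self) -> bool:
        """Whether a read taken from the upstream side of the cut (reverse
        complemented) is guaranteed to begin with the remnant."""
        return _guaranteed_prefix(revcomp(self.site[: self.cut_offset]), self.remnant)

    def cut_position(self, start: int, strand: str = "+") -> int:
        """Top-strand cut coordinate for a site match at ``start``."""
        if strand == "+":
            return start + self.cut_offset
        return start + len(self.site) - self.cut_offset

    def blocking_at(self, start: int, strand: str = "+") -> list[tuple[int, str]]:
        """Genomic (position, strand) of the blocking cytosines of a match."""
        if strand == "+":
            return [(start + o, s) for o, s in self.blocking]
        L = len(self.site)
        return [(start + L - 1 - o, "-" if s == "+" else "+") for o, s in self.blocking]

    def site_start_from_cut(self, cut: int, strand: str = "+") -> int:
        """Inverse of :meth:`cut_position`."""
        if strand == "+":
            return cut - self.cut_offset
        return cut - (len(self.site) - self.cut_offset)

    def find_sites(self, sequence: str) -> list[SiteMatch]:
        return find_sites(sequence, self)


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[SiteMatch]:
    """All recognition-site matches (0-based starts), overlapping included.

    For non-palindromic enzymes the reverse-complement orientation is scanned
    too and flagged with strand '-'.
    """
    if not sequence:
        return []
    hits = [SiteMatch(m.start(), "+")
            for m in re.finditer(f"(?=({iupac_regex(enzyme.site)}))", sequence)]
    if not enzyme.palindromic:
        rc = iupac_regex(revcomp(enzyme.site))
        hits += [SiteMatch(m.start(), "-") for m in re.finditer(f"(?=({rc}))", sequence)]
        hits.sort()
    return hits


# Built-in registry.  AciI's CCGC site is the enzyme's standard definition;
# blocking positions follow the context each library is designed to read out.
BUILTIN_ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e
    for e in [
        EnzymeSpec("MseI", "TTAA", 1),
        EnzymeSpec("AciI", "CCGC", 1, ((1, "+"), (2, "-")), True),
        EnzymeSpec("Fnu4HI", "GCNGC", 2, ((1, "+"), (3, "-")), True),
        EnzymeSpec("EcoT22I", "ATGCAT", 5, ((3, "+"), (2, "-")), True),
    ]
}

#: sensitive enzyme assigned to each methylation context
CONTEXT_ENZYME = {"CG": "AciI", "CHH": "EcoT22I", "CHG": "Fnu4HI"}


class EnzymeRegistry(dict):
    """Name -> EnzymeSpec mapping; raises a registry error on unknown names."""

    def get_enzyme(self, name: str) -> EnzymeSpec:
        try:
            return self[name]
        except KeyError:
            raise KeyError(f"enzyme {name!r} not in registry "
                           f"(known: {sorted(self)})") from None

    @classmethod
    def builtin(cls) -> "EnzymeRegistry":
        return cls(BUILTIN_ENZYMES)

    def load_tsv(self, path: str | Path) -> None:
        """Override/extend from a TSV: name, site, offset, block positions.

        Block positions are comma-separated ``<pos><strand>`` tokens,
        e.g. ``1+,2-``; an empty field means methylation-insensitive.
        """
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, site, offset = parts[0], parts[1], int(parts[2])
            blocking: tuple[tuple[int, str], ...] = ()
            if len(parts) > 3 and parts[3]:
                blocking = tuple(
                    (int(tok[:-1]), tok[-1]) for tok in parts[3].split(",")
                )
            self[name] = EnzymeSpec(name, site, offset, blocking, bool(blocking))


DEFAULT_REGISTRY = EnzymeRegistry.builtin()
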