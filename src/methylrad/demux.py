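"""Demultiplexing by in-line barcode + restriction remnant, and read QC.

Reads carry a 7-bp sample barcode followed by the remnant the library's
methylation-sensitive enzyme leaves at the cut.  A read is assigned to a
sample iff its barcode prefix matches exactly one sheet barcode within the
mismatch tolerance AND (by default) the bases after the barcode equal the
expected remnant (N in a remnant is a wildcard).  The barcode is trimmed
from the output; the remnant is retained because it is genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .enzymes import CONTEXT_ENZYME, DEFAULT_REGISTRY, IUPAC


@dataclass(frozen=True)
class SampleSheetRow:
    sample: str
    group: str  # true_to_type | off_type
    context: str  # CG | CHH | CHG
    barcode: str
    remnant: str


class SampleSheetError(ValueError):
    pass


@dataclass
class SampleSheet:
    rows: list[SampleSheetRow]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, registry=DEFAULT_REGISTRY) -> None:
        by_library: dict[str, list[SampleSheetRow]] = {}
        for row in self.rows:
            by_library.setdefault(row.context, []).append(row)
            if row.group not in ("true_to_type", "off_type"):
                raise SampleSheetError(f"unknown group {row.group!r}")
            if set(row.barcode) - set("ACGT"):
                raise SampleSheetError(f"barcode {row.barcode!r} has non-ACGT characters")
            enzyme = registry.get_enzyme(CONTEXT_ENZYME[row.context])
            if row.remnant != enzyme.remnant:
                raise SampleSheetError(
                    f"{row.sample}: remnant {row.remnant!r} inconsistent with "
                    f"{enzyme.name} cut ({enzyme.remnant!r})"
                )
        for context, rows in by_library.items():
            barcodes = [r.barcode for r in rows]
            if len(set(barcodes)) != len(barcodes):
                raise SampleSheetError(f"duplicate barcodes in {context} library")
            if len(set(len(b) for b in barcodes)) > 1:
                raise SampleSheetError(f"barcode lengths differ in {context} library")

    def library(self, context: str) -> list[SampleSheetRow]:
        return [r for r in self.rows if r.context == context]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.rows]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t")
        return cls([SampleSheetRow(**row) for row in df.to_dict("records")])


def _remnant_matches(seq: str, remnant: str) -> bool:
    if len(seq) < len(remnant):
        return False
    return all(s in IUPAC[r] for s, r in zip(seq, remnant))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads,
    sheet_rows: list[SampleSheetRow],
    max_barcode_mismatch: int = 0,
    require_remnant: bool = True,
):
    """Assign pooled reads of one library to samples.

    ``reads`` yields (id, sequence, quality) tuples.  Returns
    (per-sample read lists with barcodes trimmed, report DataFrame with
    assigned / unassigned-by-reason counts).  With a mismatch tolerance the
    match must be unique (unique-decoding check), else the read is
    unassigned with reason ``ambiguous``.
    """
    if not sheet_rows:
        raise SampleSheetError("empty sample sheet")
    bc_len = len(sheet_rows[0].barcode)
    barcodes = {r.barcode: r for r in sheet_rows}
    if len(barcodes) != len(sheet_rows):
        raise SampleSheetError("duplicate barcodes")

    assigned: dict[str, list[tuple[str, str, str]]] = {r.sample: [] for r in sheet_rows}
    counts = {r.sample: 0 for r in sheet_rows}
    unassigned = {"barcode": 0, "ambiguous": 0, "remnant": 0, "too_short": 0}

    for rid, seq, qual in reads:
        if len(seq) <= bc_len:
            unassigned["too_short"] += 1
            continue
        prefix = seq[:bc_len]
        row = barcodes.get(prefix)
        if row is None and max_barcode_mismatch > 0:
            hits = [
                r for b, r in barcodes.items()
                if _hamming(prefix, b) <= max_barcode_mismatch
            ]
            if len(hits) > 1:
                unassigned["ambiguous"] += 1
                continue
            row = hits[0] if hits else None
        if row is None:
            unassigned["barcode"] += 1
            continue
        rest, rest_q = seq[bc_len:], qual[bc_len:]
        if require_remnant and not _remnant_matches(rest, row.remnant):
            unassigned["remnant"] += 1
            continue
        assigned[row.sample].append((rid, rest, rest_q))
        counts[row.sample] += 1

    report = pd.DataFrame(
        [{"record": r.sample, "kind": "assigned", "reads": counts[r.sample]} for r in sheet_rows]
        + [
            {"record": f"unassigned:{reason}", "kind": "unassigned", "reads": n}
            for reason, n in unassigned.items()
        ]
    )
    return assigned, report


def demux_totals(report: pd.DataFrame) -> dict[str, int]:
    assigned = int(report.loc[report["kind"] == "assigned", "reads"].sum())
    unassigned = int(report.loc[report["kind"] == "unassigned", "reads"].sum())
    return {"assigned": assigned, "unassigned": unassigned, "total": assigned + unassigned}


def quality_trim(
    seq: str,
    qual: str,
    window: int = 10,
    q_threshold: float = 20.0,
    min_len: int = 40,
) -> tuple[str, str] | None:
    """3' truncation at the first non-overlapping window of mean quality
    below threshold; returns None (discard) if the trimmed read is shorter
    than ``min_len``.  Qualities are Phred+33."""
    if len(seq) != len(qual):
        raise ValueError("sequence and quality lengths differ")
    scores = [ord(c) - 33 for c in qual]
    cut = len(seq)
    for start in range(0, len(seq), window):
        chunk = scores[start : start + window]
        if sum(chunk) / len(chunk) < q_threshold:
            cut = start
            break
    if cut < min_len:
        return None
    return seq[:cut], qual[:cut]


def adapter_trim(
    seq: str, qual: str, adapter: str, min_overlap: int = 8
) -> tuple[str, str]:
    """Remove the longest read suffix exactly matching an adapter prefix."""
    if set(adapter) - set("ACGT"):
        raise ValueError("adapter must be over ACGT")
    for k in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k], qual[:-k]
    return seq, qual
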