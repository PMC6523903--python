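"""Pseudo-reference construction: cluster reads into loci and count them.

Reads of one library share a 5' anchor (the restriction remnant), so
clustering is ungapped and 5'-anchored: reads are processed longest-first
(ties broken lexicographically); a read joins the first existing centroid
whose identity over the overlap is >= the threshold, otherwise it founds a
new centroid.  The locus consensus is the per-position majority over member
reads (ties resolved toward the centroid base).  Counting then assigns each
sample's reads to the best-identity locus at the same threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _encode(seq: str, width: int) -> np.ndarray:
    arr = np.zeros(width, dtype=np.uint8)
    b = seq.encode()
    arr[: len(b)] = np.frombuffer(b, dtype=np.uint8)
    return arr


class _CentroidStore:
    """Growable matrix of 5'-anchored centroid sequences (0-padded)."""

    def __init__(self, width: int):
        self.width = width
        self.matrix = np.zeros((0, width), dtype=np.uint8)
        self.lengths = np.zeros(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.lengths)

    def add(self, seq: str) -> int:
        row = _encode(seq, self.width)
        self.matrix = np.vstack([self.matrix, row[None, :]])
        self.lengths = np.append(self.lengths, len(seq))
        return len(self.lengths) - 1

    def identities(self, seq: str) -> np.ndarray:
        """Ungapped identity of ``seq`` to every centroid over the overlap."""
        if not len(self.lengths):
            return np.zeros(0)
        if len(seq) > self.width:
            seq = seq[: self.width]
        q = _encode(seq, self.width)
        overlap = np.minimum(self.lengths, len(seq))
        eq = self.matrix == q[None, :]
        pos = np.arange(self.width)[None, :]
        matches = (eq & (pos < overlap[:, None])).sum(axis=1)
        return matches / np.maximum(overlap, 1)


@dataclass
class LocusCatalog:
    """Clustered loci of one library with consensus sequences."""

    consensus: list[str]
    member_counts: list[int]
    identity_threshold: float = 0.90

    def __len__(self) -> int:
        return len(self.consensus)

    def locus_id(self, index: int) -> str:
        return f"L{index + 1:06d}"

    @property
    def locus_ids(self) -> list[str]:
        return [self.locus_id(i) for i in range(len(self.consensus))]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lid, seq, n in zip(self.locus_ids, self.consensus, self.member_counts):
                fh.write(f">{lid} members={n}\n{seq}\n")


def cluster_reads(
    reads: list[str],
    identity_threshold: float = 0.90,
) -> LocusCatalog:
    """Greedy centroid clustering of (already trimmed, remnant-anchored) reads."""
    if not reads:
        return LocusCatalog([], [], identity_threshold)
    multiplicity = Counter(reads)
    unique = sorted(multiplicity, key=lambda s: (-len(s), s))
    width = len(unique[0])
    store = _CentroidStore(width)
    # per-centroid per-position base tallies for the majority consensus
    tallies: list[np.ndarray] = []
    members: list[int] = []
    for seq in unique:
        weight = multiplicity[seq]
        ids = store.identities(seq)
        hit = np.nonzero(ids >= identity_threshold)[0]
        if hit.size:
            c = int(hit[0])  # first centroid in creation order
        else:
            c = store.add(seq)
            tallies.append(np.zeros((4, width), dtype=np.int64))
            members.append(0)
        enc = _encode(seq, width)
        for bi, base in enumerate(b"ACGT"):
            tallies[c][bi, : len(seq)] += (enc[: len(seq)] == base) * weight
        members[c] += weight

    consensus = []
    for c in range(len(store)):
        clen = int(store.lengths[c])
        tally = tallies[c][:, :clen]
        best = tally.argmax(axis=0)
        maxed = tally.max(axis=0)
        cent = store.matrix[c, :clen]
        cons = np.frombuffer(b"ACGT", dtype=np.uint8)[best].copy()
        # ties (or positions beyond all members) fall back to the centroid base
        cent_counts = tally[
            np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), cent), np.arange(clen)
        ]
        tie = cent_counts == maxed
        cons[tie] = cent[tie]
        consensus.append(cons.tobytes().decode())
    return LocusCatalog(consensus, members, identity_threshold)


@dataclass
class CountMatrix:
    """Loci x samples integer counts plus per-sample library sizes."""

    counts: pd.DataFrame  # index = locus ids, columns = samples
    library_sizes: pd.Series
    unassigned: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        header = pd.DataFrame(
            [self.library_sizes, self.unassigned], index=["#library_size", "#unassigned"]
        )
        pd.concat([header, out]).to_csv(path, sep="\t", index_label="locus")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus")
        lib = df.loc["#library_size"].astype(int)
        unassigned = df.loc["#unassigned"].astype(int)
        counts = df.drop(index=["#library_size", "#unassigned"]).astype(int)
        counts.index.name = None
        return cls(counts, lib, unassigned)


def assign_and_count(
    catalog: LocusCatalog,
    reads_by_sample: dict[str, list[str]],
    identity_threshold: float | None = None,
) -> CountMatrix:
    """Assign each read to its best-identity locus and tabulate counts.

    Reads below the identity threshold are counted as unassigned.  Ties go
    to the lowest locus id (centroid creation order).  Column sums equal
    per-sample assigned read counts by construction.
    """
    thr = identity_threshold if identity_threshold is not None else catalog.identity_threshold
    width = max((len(s) for s in catalog.consensus), default=0)
    store = _CentroidStore(max(width, 1))
    for seq in catalog.consensus:
        store.add(seq)
    cache: dict[str, int] = {}
    samples = list(reads_by_sample)
    mat = np.zeros((len(catalog), len(samples)), dtype=np.int64)
    unassigned = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        for seq in reads_by_sample[sample]:
            locus = cache.get(seq, -2)
            if locus == -2:
                ids = store.identities(seq)
                if ids.size and ids.max() >= thr:
                    locus = int(ids.argmax())  # argmax -> lowest index on ties
                else:
                    locus = -1
                cache[seq] = locus
            if locus >= 0:
                mat[locus, j] += 1
            else:
                unassigned[j] += 1
    counts = pd.DataFrame(mat, index=catalog.locus_ids, columns=samples)
    return CountMatrix(
        counts,
        counts.sum(axis=0),
        pd.Series(unassigned, index=samples),
    )


def drop_low_support(matrix: CountMatrix, floor: int = 3) -> CountMatrix:
    """Drop loci whose total count across all samples is below ``floor``."""
    keep = matrix.counts.sum(axis=1) >= floor
    return CountMatrix(matrix.counts.loc[keep], matrix.library_sizes, matrix.unassigned)
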