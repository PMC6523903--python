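"""Follow-up analytics: miRNA-target expectation scoring, interaction-network
statistics and ddCT relative-quantification of transcript levels.

The miRNA scorer is a simplified plant-target predictor: the mature miRNA is
aligned antisense and ungapped against every window of a transcript; each
position contributes 0 for a Watson-Crick pair, 0.5 for a G:U wobble and 1.0
for a mismatch, with penalties doubled inside the core (miRNA positions
2-13, counted from the 5' end).  A hit is reported when the summed
expectation E does not exceed the threshold (default 5); a non-Watson-Crick
pair at positions 10-11 flags translational inhibition instead of cleavage.
The penalty constants follow the common published convention; only the
threshold and the 10-11 rule are fixed by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .stats import locus_ttest

CORE = range(2, 14)  # miRNA positions with doubled penalties (1-based, 2..13)
INHIBITION_POSITIONS = (10, 11)


class TargetHit(NamedTuple):
    mirna_id: str
    gene_id: str
    position: int  # alignment start in the target (0-based)
    expectation: float
    mode: str  # cleavage | translation_inhibition


def _norm_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"{what} contains non-nucleotide characters")
    return s


def _pair_kind(mir_base: str, target_base: str) -> str:
    if (mir_base, target_base) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return "wc"
    if (mir_base, target_base) in (("G", "T"), ("T", "G")):
        return "wobble"
    return "mismatch"


def score_mirna_target(
    mirna: str,
    target: str,
    mirna_id: str = "miRNA",
    gene_id: str = "gene",
    max_expectation: float = 5.0,
    mismatch_penalty: float = 1.0,
    wobble_penalty: float = 0.5,
    core_multiplier: float = 2.0,
) -> TargetHit | None:
    """Best ungapped antisense alignment of a miRNA to a target sequence.

    Returns the lowest-expectation window as a :class:`TargetHit`, or None
    when no window scores within ``max_expectation``.
    """
    m = _norm_rna(mirna, "miRNA")
    t = _norm_rna(target, "target")
    if not 19 <= len(m) <= 24:
        raise ValueError("miRNA length must be 19-24 nt")
    if len(t) < len(m):
        raise ValueError("target window shorter than the miRNA")
    L = len(m)
    best: tuple[float, int, bool] | None = None
    for start in range(len(t) - L + 1):
        window = t[start : start + L]
        E = 0.0
        noncanonical_core = False
        for i in range(L):  # i: 0-based; miRNA position = i + 1 from the 5' end
            # antiparallel pairing: miRNA 5' base pairs the window's 3' base
            kind = _pair_kind(m[i], window[L - 1 - i])
            if kind == "wc":
                continue
            if (i + 1) in INHIBITION_POSITIONS:
                noncanonical_core = True
            pen = mismatch_penalty if kind == "mismatch" else wobble_penalty
            if (i + 1) in CORE:
                pen *= core_multiplier
            E += pen
        if best is None or E < best[0]:
            best = (E, start, noncanonical_core)
    E, start, inhib = best
    if E > max_expectation:
        return None
    mode = "translation_inhibition" if inhib else "cleavage"
    return TargetHit(mirna_id, gene_id, start, E, mode)


def scan_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_expectation: float = 5.0,
) -> pd.DataFrame:
    """All miRNA x transcript hits within the expectation threshold."""
    rows = []
    for mid, mseq in mirnas.items():
        for gid, tseq in transcripts.items():
            if len(tseq) < len(mseq.replace("U", "T")):
                continue
            hit = score_mirna_target(mseq, tseq, mid, gid, max_expectation)
            if hit is not None:
                rows.append(hit._asdict())
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "position", "expectation", "mode"]
    )


class NetworkSummary(NamedTuple):
    n_nodes: int
    n_edges: int
    average_degree: float  # 2E/N, rounded to 2 decimals on report


def network_stats(edges: Iterable[tuple[str, str]]) -> NetworkSummary:
    """Node/edge counts and average node degree of a simple undirected graph.

    Self-loops are rejected with a warning; duplicate edges collapse.
    """
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            warnings.warn(f"self-loop {a!r} rejected", stacklevel=2)
            continue
        g.add_edge(a, b)
    n, e = g.number_of_nodes(), g.number_of_edges()
    avg = round(2 * e / n, 2) if n else 0.0
    return NetworkSummary(n, e, avg)


@dataclass
class DdctResult:
    per_sample: pd.DataFrame  # gene, sample, group, dct, ddct, fold_change
    per_gene: pd.DataFrame  # gene, fold change by group, t, p


def ddct(
    records: pd.DataFrame,
    reference_assays: tuple[str, str] = ("ACT", "EF1"),
    calibrator_group: str = "true_to_type",
) -> DdctResult:
    """Relative quantification by the ddCT method.

    ``records`` is tidy qPCR data with columns gene, sample, group, assay,
    replicate, ct (three technical replicates per assay are averaged first).
    Reference CT per sample is the arithmetic mean of the two reference-assay
    means; dCT = CT_target - CT_ref per biological replicate;
    ddCT = dCT - mean dCT of the calibrator group; fold change = 2^-ddCT.
    Groups are compared per gene by a two-sample t-test on dCT values.
    """
    required = {"gene", "sample", "group", "assay", "ct"}
    if missing := required - set(records.columns):
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    tech_mean = (
        records.groupby(["gene", "sample", "group", "assay"], observed=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = tech_mean[tech_mean["assay"].isin(reference_assays)]
    ref_ct = ref.groupby("sample")["ct"].agg(["mean", "count"])
    targets = tech_mean[~tech_mean["assay"].isin(reference_assays)]

    rows = []
    for row in targets.itertuples(index=False):
        if row.sample not in ref_ct.index or ref_ct.loc[row.sample, "count"] < len(
            reference_assays
        ):
            warnings.warn(
                f"sample {row.sample}: missing reference assay, record skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "gene": row.gene,
                "sample": row.sample,
                "group": row.group,
                "dct": row.ct - ref_ct.loc[row.sample, "mean"],
            }
        )
    per_sample = pd.DataFrame(rows)
    out_genes = []
    frames = []
    for gene, sub in per_sample.groupby("gene"):
        calib = sub.loc[sub["group"] == calibrator_group, "dct"]
        if calib.empty:
            raise ValueError(f"{gene}: calibrator group {calibrator_group!r} absent")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - calib.mean()
        sub["fold_change"] = 2.0 ** (-sub["ddct"])
        frames.append(sub)
        groups = [g for g in sub["group"].unique() if g != calibrator_group]
        for other in groups:
            res = locus_ttest(
                sub.loc[sub["group"] == calibrator_group, "dct"],
                sub.loc[sub["group"] == other, "dct"],
            )
            fc_other = sub.loc[sub["group"] == other, "fold_change"].mean()
            out_genes.append(
                {
                    "gene": gene,
                    "group": other,
                    "fold_change_vs_calibrator": fc_other,
                    "t": res.t,
                    "p": res.p,
                    "regulation": "down" if fc_other < 1 else "up",
                }
            )
    return DdctResult(
        pd.concat(frames, ignore_index=True) if frames else per_sample,
        pd.DataFrame(out_genes),
    )
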