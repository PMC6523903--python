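"""Statistical core: normalization, locus filtering, QC ordination and
exact-test calling of differentially methylated loci (DML).

The analysis chain mirrors presence/absence methylation profiling with a
methylation-sensitive reduced-representation assay:

1. counts-per-million normalization by library size;
2. a per-locus pooled-variance t-test with Benjamini-Hochberg correction
   removes loci inconsistent within groups ("biased loci"); loci at
   FDR < 0.05 feed PCA and average-linkage clustering QC;
3. an exact test on per-group aggregated counts (Fisher by default, a
   negative-binomial conditional exact test optionally) calls DML at
   p < 0.01;
4. direction follows the assay inversion: more reads = less methylation,
   so mean CPM_TT > mean CPM_OT means the locus is hypo-methylated in the
   true-to-type group.

Group counts are aggregated by summation (with summed library sizes):
for Poisson sampling noise the Fisher test on sums is exactly calibrated,
which rounded per-group means are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .catalog import CountMatrix
from .synthetic import StudyDesign

PSEUDOCOUNT = 0.5


@dataclass
class NormalizedMatrix:
    """CPM values (loci x samples) plus per-locus log2 fold change TT/OT."""

    cpm: pd.DataFrame
    log2fc: pd.Series
    excluded_samples: list[str]


def cpm_normalize(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    design: StudyDesign | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> NormalizedMatrix:
    """value = 1e6 * count / library size; zero-size columns are excluded."""
    ok = library_sizes > 0
    excluded = [s for s in counts.columns if not ok.get(s, False)]
    used = [s for s in counts.columns if ok.get(s, False)]
    cpm = counts[used] * 1e6 / library_sizes[used]
    if design is not None:
        tt = [s for s in used if design.group_of(s) == "true_to_type"]
        ot = [s for s in used if design.group_of(s) == "off_type"]
        log2fc = np.log2(
            (cpm[tt].mean(axis=1) + pseudocount) / (cpm[ot].mean(axis=1) + pseudocount)
        )
    else:
        log2fc = pd.Series(np.nan, index=counts.index)
    return NormalizedMatrix(cpm, log2fc, excluded)


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool


def locus_ttest(values_a: Iterable[float], values_b: Iterable[float]) -> TTestResult:
    """Two-sample pooled-variance Student's t-test (two-sided).

    Degenerate case: both groups have zero variance.  Equal means then give
    p = 1; unequal means give p -> 0 and the result is flagged.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, False)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0, True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), False)


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Step-up BH adjusted q-values, original order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def groupwise_ttests(
    cpm: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Per-locus pooled t-test of CPM between the two groups (vectorized)."""
    tt = [s for s in cpm.columns if design.group_of(s) == "true_to_type"]
    ot = [s for s in cpm.columns if design.group_of(s) == "off_type"]
    a = cpm[tt].to_numpy(float)
    b = cpm[ot].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    df = na + nb - 2
    p = 2 * sps.t.sf(np.abs(t), df)
    degenerate = (se == 0) & (ma != mb)
    p = np.where(se == 0, np.where(ma == mb, 1.0, 0.0), p)
    t = np.where((se == 0) & (ma == mb), 0.0, t)
    return pd.DataFrame(
        {"t": t, "p": p, "degenerate": degenerate}, index=cpm.index
    )


def prefilter_loci(
    norm: NormalizedMatrix, design: StudyDesign, fdr: float = 0.05
) -> pd.Index:
    """Loci whose group difference survives BH at the given FDR.

    These "high-quality" loci feed the QC ordination and the exact test.
    """
    tests = groupwise_ttests(norm.cpm, design)
    q = benjamini_hochberg(tests["p"])
    return norm.cpm.index[q < fdr]


def pca_scores(values: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample ordination of a loci x samples matrix by centered SVD.

    Returns (scores: samples x components, explained-variance fractions).
    Fractions are non-increasing and sum to 1.
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = values.to_numpy(float).T  # samples x loci
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2
    total = var.sum()
    fractions = var / total if total > 0 else np.full_like(var, 1 / len(var))
    scores = pd.DataFrame(
        U * S,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(len(S))],
    )
    return scores, fractions


def average_linkage_cluster(
    values: pd.DataFrame | None = None,
    condensed_distances: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """UPGMA (average linkage) on Euclidean distances.

    Accepts either a matrix of row vectors or a precomputed condensed
    distance vector.  Returns (scipy linkage matrix, leaf order).
    """
    if condensed_distances is None:
        if values is None or len(values) < 2:
            raise ValueError("need >= 2 rows")
        condensed_distances = pdist(values.to_numpy(float), metric="euclidean")
    Z = hierarchy.linkage(condensed_distances, method="average")
    order = hierarchy.leaves_list(Z).tolist()
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        i, j = int(i), int(j)
        left = f"{nodes[i]}:{h / 2 - heights[i] / 2:.6g}"
        right = f"{nodes[j]}:{h / 2 - heights[j] / 2:.6g}"
        nodes[n + k] = f"({left},{right})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def exact_test(
    count_sum_a: int,
    count_sum_b: int,
    lib_a: int,
    lib_b: int,
    method: str = "fisher",
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact test of equal per-library abundance.

    fisher:   Fisher's exact test on [[a, libA-a], [b, libB-b]] (two-sided =
              sum of table probabilities <= the observed one).
    nb_exact: conditional exact test of a given n = a + b under negative
              binomial counts with common dispersion phi and means
              proportional to library sizes; phi = 0 reduces to the exact
              binomial test with proportion libA / (libA + libB).
    """
    a, b = int(count_sum_a), int(count_sum_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a > lib_a or b > lib_b:
        raise ValueError("counts exceed library sizes")
    if method == "fisher":
        return float(
            sps.fisher_exact([[a, lib_a - a], [b, lib_b - b]], alternative="two-sided")[1]
        )
    if method != "nb_exact":
        raise ValueError(f"unknown method {method!r}")
    n = a + b
    if n == 0:
        return 1.0
    frac = lib_a / (lib_a + lib_b)
    mu_a, mu_b = n * frac, n * (1 - frac)
    k = np.arange(n + 1)
    if dispersion <= 0:
        logw = sps.poisson.logpmf(k, mu_a) + sps.poisson.logpmf(n - k, mu_b)
    else:
        r = 1.0 / dispersion
        logw = sps.nbinom.logpmf(k, r, r / (r + mu_a)) + sps.nbinom.logpmf(
            n - k, r, r / (r + mu_b)
        )
    w = np.exp(logw - logw.max())
    observed = w[a]
    p = w[w <= observed * (1 + 1e-12)].sum() / w.sum()
    return float(min(1.0, p))


def estimate_common_dispersion(
    counts: pd.DataFrame, design: StudyDesign, grid: np.ndarray | None = None
) -> float:
    """Common NB dispersion by maximizing the summed conditional
    log-likelihood of within-group splits over a phi grid."""
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 2.0, 40)])
    groups = [design.samples_of(g) for g in design.groups]
    best_phi, best_ll = 0.0, -np.inf
    data = [counts[[s for s in g if s in counts.columns]].to_numpy(int) for g in groups]
    for phi in grid:
        ll = 0.0
        for mat in data:
            n_s = mat.shape[1]
            if n_s < 2:
                continue
            totals = mat.sum(axis=1)
            for row, total in zip(mat, totals):
                if total == 0:
                    continue
                # conditional likelihood of the first sample's share
                k = np.arange(total + 1)
                if phi == 0:
                    logw = sps.binom.logpmf(k, total, 1 / n_s)
                else:
                    r = 1.0 / phi
                    mu1, mu2 = total / n_s, total * (n_s - 1) / n_s
                    logw = sps.nbinom.logpmf(k, r, r / (r + mu1)) + sps.nbinom.logpmf(
                        total - k, r * (n_s - 1), r * (n_s - 1) / (r * (n_s - 1) + mu2)
                    )
                norm = np.logaddexp.reduce(logw)
                ll += logw[row[0]] - norm
        if ll > best_ll:
            best_ll, best_phi = ll, float(phi)
    return best_phi


def exact_test_table(
    matrix: CountMatrix,
    design: StudyDesign,
    method: str = "fisher",
    aggregate: str = "sum",
    dispersion: float = 0.0,
    loci: pd.Index | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-locus exact-test table (p, log2FC, direction) without thresholding."""
    counts = matrix.counts if loci is None else matrix.counts.loc[loci]
    tt = [s for s in counts.columns if design.group_of(s) == "true_to_type"]
    ot = [s for s in counts.columns if design.group_of(s) == "off_type"]
    if not tt or not ot:
        raise ValueError("both groups must be present in the count matrix")
    lib = matrix.library_sizes
    if aggregate == "sum":
        agg_a = counts[tt].sum(axis=1).astype(int)
        agg_b = counts[ot].sum(axis=1).astype(int)
        lib_a, lib_b = int(lib[tt].sum()), int(lib[ot].sum())
    elif aggregate == "mean":
        agg_a = counts[tt].mean(axis=1).round().astype(int)
        agg_b = counts[ot].mean(axis=1).round().astype(int)
        lib_a, lib_b = int(round(lib[tt].mean())), int(round(lib[ot].mean()))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    p = np.array(
        [
            exact_test(a, b, lib_a, lib_b, method=method, dispersion=dispersion)
            for a, b in zip(agg_a, agg_b)
        ]
    )
    cpm_a = counts[tt].to_numpy(float).mean(axis=1) * 1e6 / (lib[tt].mean())
    cpm_b = counts[ot].to_numpy(float).mean(axis=1) * 1e6 / (lib[ot].mean())
    log2fc = np.log2((cpm_a + pseudocount) / (cpm_b + pseudocount))
    # more reads = less methylation: TT-enriched loci are hypo-methylated in TT
    direction = np.where(cpm_a > cpm_b, "hypo_in_TT", "hyper_in_TT")
    return pd.DataFrame(
        {
            "mean_count_tt": counts[tt].mean(axis=1),
            "mean_count_ot": counts[ot].mean(axis=1),
            "p": p,
            "log2fc": log2fc,
            "direction": direction,
        },
        index=counts.index,
    )


def call_dml(
    matrix: CountMatrix,
    design: StudyDesign,
    alpha: float = 0.01,
    method: str = "fisher",
    aggregate: str = "sum",
    dispersion: float = 0.0,
    loci: pd.Index | None = None,
) -> pd.DataFrame:
    """DML table: loci whose exact-test p is below ``alpha``."""
    table = exact_test_table(matrix, design, method, aggregate, dispersion, loci)
    return table[table["p"] < alpha].copy()


def direction_summary(dml: pd.DataFrame, by_context: bool = True) -> pd.DataFrame:
    """Hypo/hyper counts and fractions (relative to true-to-type).

    Expects a DataFrame with a ``direction`` column and, when summarizing per
    context, a ``context`` column.  ``percent`` is rounded to the nearest
    integer for reporting.
    """
    if dml.empty:
        cols = ["context"] if by_context else []
        return pd.DataFrame(
            columns=cols + ["direction", "count", "fraction", "percent"]
        )
    keys = ["context", "direction"] if by_context and "context" in dml else ["direction"]
    counts = dml.groupby(keys, observed=True).size().rename("count").reset_index()
    group_keys = ["context"] if "context" in counts else []
    if group_keys:
        totals = counts.groupby(group_keys)["count"].transform("sum")
    else:
        totals = counts["count"].sum()
    counts["fraction"] = counts["count"] / totals
    counts["percent"] = (100 * counts["fraction"]).round().astype(int)
    return counts
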