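import math

import numpy as np
import pandas as pd
import pytest

from methylrad.catalog import CountMatrix
from methylrad.stats import (
    average_linkage_cluster,
    benjamini_hochberg,
    call_dml,
    cpm_normalize,
    direction_summary,
    exact_test,
    groupwise_ttests,
    linkage_to_newick,
    locus_ttest,
    pca_scores,
    prefilter_loci,
    exact_test_table,
)
from methylrad.synthetic import StudyDesign

SAMPLES = ["TT1", "TT2", "TT3", "OT1", "OT2", "OT3"]


def _matrix(tt_rows, ot_rows, index=None):
    """Build a CountMatrix from per-locus (TT counts, OT counts) rows."""
    data = np.hstack([np.asarray(tt_rows), np.asarray(ot_rows)])
    counts = pd.DataFrame(data, columns=SAMPLES, index=index)
    lib = counts.sum() + 1000  # library sizes exceed any locus count
    return CountMatrix(counts, lib, pd.Series(0, index=SAMPLES))


# ---------------------------------------------------------------- CPM


def test_cpm_values():
    counts = pd.DataFrame({"s1": [10], "s2": [90]})
    norm = cpm_normalize(counts, pd.Series({"s1": 100, "s2": 100}))
    assert norm.cpm.loc[0, "s1"] == 1e5
    assert norm.cpm.loc[0, "s2"] == 9e5


def test_cpm_scale_invariance_and_zero_rows():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [90, 0]})
    lib = pd.Series({"s1": 200, "s2": 400})
    a = cpm_normalize(counts, lib)
    b = cpm_normalize(counts * 2, lib * 2)
    pd.testing.assert_frame_equal(a.cpm, b.cpm)
    assert (a.cpm.iloc[1] == 0).all()


def test_cpm_columns_sum_to_million():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.poisson(20, (50, 4)), columns=list("abcd"))
    norm = cpm_normalize(counts, counts.sum())
    assert np.allclose(norm.cpm.sum(), 1e6)


def test_cpm_zero_library_flagged_excluded():
    counts = pd.DataFrame({"s1": [5], "s2": [0]})
    norm = cpm_normalize(counts, pd.Series({"s1": 10, "s2": 0}))
    assert norm.excluded_samples == ["s2"]
    assert list(norm.cpm.columns) == ["s1"]


# ---------------------------------------------------------------- t-test


def test_ttest_identical_groups():
    assert locus_ttest([1, 2, 3], [1, 2, 3]) == (0.0, 1.0, False)


def test_ttest_closed_form_value():
    res = locus_ttest([1, 2, 3], [2, 3, 4])
    assert res.t == pytest.approx(-1.2247, abs=1e-4)
    assert res.p == pytest.approx(0.2879, abs=1e-4)


def test_ttest_degenerate_zero_variance():
    res = locus_ttest([0, 0, 0], [5, 5, 5])
    assert res.degenerate and res.p == 0.0


def test_ttest_requires_two_per_group():
    with pytest.raises(ValueError):
        locus_ttest([1], [2, 3])


def test_vectorized_ttests_match_scalar():
    rng = np.random.default_rng(3)
    cpm = pd.DataFrame(rng.normal(10, 2, (20, 6)), columns=SAMPLES)
    table = groupwise_ttests(cpm, StudyDesign())
    for locus in cpm.index:
        res = locus_ttest(cpm.loc[locus, SAMPLES[:3]], cpm.loc[locus, SAMPLES[3:]])
        assert table.loc[locus, "t"] == pytest.approx(res.t)
        assert table.loc[locus, "p"] == pytest.approx(res.p)


# ---------------------------------------------------------------- BH


def _bh_oracle(p):
    """Step-up definition: q_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def test_bh_examples():
    assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    assert benjamini_hochberg([0.123]).tolist() == [0.123]


def test_bh_matches_step_up_definition_on_random_vectors():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        p = rng.random(int(rng.integers(1, 30)))
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p), atol=1e-12)


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


# ---------------------------------------------------------------- exact tests


def _fisher_oracle(a, b, la, lb):
    """Hypergeometric enumeration over all tables with the observed margins."""
    n = a + b
    row1 = la
    total = la + lb
    probs = []
    for k in range(max(0, n - lb), min(n, la) + 1):
        probs.append(
            (k, math.comb(row1, k) * math.comb(total - row1, n - k) / math.comb(total, n))
        )
    obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= obs * (1 + 1e-9))


def test_fisher_example_value():
    # [[5,0],[0,5]]: two-sided p = 2/252
    assert exact_test(5, 0, 5, 5) == pytest.approx(2 / 252)


def test_fisher_symmetry_p_one():
    assert exact_test(7, 7, 100, 100) == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration_sampled():
    rng = np.random.default_rng(5)
    for _ in range(300):
        total = int(rng.integers(2, 41))
        la = int(rng.integers(1, total))
        lb = total - la
        a = int(rng.integers(0, la + 1))
        b = int(rng.integers(0, lb + 1))
        assert exact_test(a, b, la, lb) == pytest.approx(
            _fisher_oracle(a, b, la, lb), rel=1e-9
        )


def _binomial_oracle(a, n, frac):
    probs = [math.comb(n, k) * frac**k * (1 - frac) ** (n - k) for k in range(n + 1)]
    obs = probs[a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))


def test_nb_exact_at_zero_dispersion_equals_binomial():
    rng = np.random.default_rng(6)
    for _ in range(200):
        la = int(rng.integers(50, 5000))
        lb = int(rng.integers(50, 5000))
        a = int(rng.integers(0, 40))
        b = int(rng.integers(0, 40))
        got = exact_test(a, b, la, lb, method="nb_exact", dispersion=0.0)
        want = _binomial_oracle(a, a + b, la / (la + lb))
        assert got == pytest.approx(want, rel=1e-6)


def test_nb_exact_dispersion_widens_tails():
    p_poisson = exact_test(30, 10, 1000, 1000, method="nb_exact", dispersion=0.0)
    p_nb = exact_test(30, 10, 1000, 1000, method="nb_exact", dispersion=0.5)
    assert p_nb > p_poisson


def test_exact_test_input_validation():
    with pytest.raises(ValueError):
        exact_test(10, 0, 5, 5)
    with pytest.raises(ValueError):
        exact_test(1, 1, 5, 5, method="chisq")


# ---------------------------------------------------------------- prefilter


def test_prefilter_retains_all_at_fdr_one(design):
    m = _matrix(np.random.default_rng(1).poisson(20, (30, 3)),
                np.random.default_rng(2).poisson(20, (30, 3)))
    norm = cpm_normalize(m.counts, m.library_sizes, design)
    assert len(prefilter_loci(norm, design, fdr=1.0)) == 30


def test_prefilter_null_retains_almost_nothing(design):
    rng = np.random.default_rng(4)
    m = _matrix(rng.poisson(20, (2000, 3)), rng.poisson(20, (2000, 3)))
    norm = cpm_normalize(m.counts, m.library_sizes, design)
    retained = prefilter_loci(norm, design, fdr=0.05)
    assert len(retained) / 2000 < 0.01


def test_prefilter_power_on_switched_loci(design):
    """Fully on/off loci at depth 20, 3v3, at the study's planted fraction
    (200 of ~800 catalog loci) are retained with probability >= 0.9."""
    rng = np.random.default_rng(9)
    n_on, n_null = 200, 600
    tt = np.vstack([rng.poisson(20, (n_on, 3)), rng.poisson(20, (n_null, 3))])
    ot = np.vstack([np.zeros((n_on, 3), int), rng.poisson(20, (n_null, 3))])
    m = _matrix(tt, ot)
    norm = cpm_normalize(m.counts, m.library_sizes, design)
    retained = set(prefilter_loci(norm, design, fdr=0.05))
    hit = sum(1 for i in range(n_on) if m.counts.index[i] in retained)
    assert hit / n_on >= 0.9


# ---------------------------------------------------------------- PCA / UPGMA


def test_pca_rank_one_matrix():
    base = np.outer([1, 2, 3, 4], [1, -1, 2, 0.5, 1, -2])
    values = pd.DataFrame(base, columns=SAMPLES)
    _, fractions = pca_scores(values)
    assert fractions[0] == pytest.approx(1.0)


def test_pca_fractions_sum_to_one(rng):
    values = pd.DataFrame(rng.normal(size=(30, 6)), columns=SAMPLES)
    scores, fractions = pca_scores(values)
    assert fractions.sum() == pytest.approx(1.0)
    assert all(x >= y for x, y in zip(fractions, fractions[1:]))
    assert list(scores.index) == SAMPLES


def test_pca_separates_groups_with_planted_effect(rng, design):
    effect = np.zeros((100, 6))
    effect[:50, :3] = 20  # TT-only signal on half the loci
    values = pd.DataFrame(rng.poisson(20, (100, 6)) + effect, columns=SAMPLES)
    scores, fractions = pca_scores(values)
    pc1 = scores["PC1"]
    assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:])) or (
        (np.sign(pc1[:3]) == np.sign(pc1[:3]).iloc[0]).all()
        and (np.sign(pc1[3:]) == -np.sign(pc1[:3]).iloc[0]).all()
    )
    assert fractions[0] > 0.5


def test_pca_needs_two_samples():
    with pytest.raises(ValueError):
        pca_scores(pd.DataFrame({"s": [1.0, 2.0]}))


def test_upgma_hand_computed_merge_heights():
    # distances A-B=1, A-C=4, B-C=5: first merge (A,B) at 1, then C at 4.5
    Z, order = average_linkage_cluster(condensed_distances=np.array([1.0, 4.0, 5.0]))
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
    assert Z[0, 2] == pytest.approx(1.0)
    assert Z[1, 2] == pytest.approx(4.5)


def test_upgma_identical_rows_merge_at_zero():
    values = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
    Z, _ = average_linkage_cluster(values)
    assert Z[0, 2] == pytest.approx(0.0)


def test_upgma_invariant_to_row_permutation(rng):
    values = pd.DataFrame(rng.normal(size=(6, 4)))
    Z1, _ = average_linkage_cluster(values)
    perm = rng.permutation(6)
    Z2, _ = average_linkage_cluster(values.iloc[perm].reset_index(drop=True))
    np.testing.assert_allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]), atol=1e-12)


def test_newick_serialization_parses():
    from io import StringIO

    from Bio import Phylo

    values = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 3)))
    Z, _ = average_linkage_cluster(values)
    nwk = linkage_to_newick(Z, ["a", "b", "c", "d"])
    tree = Phylo.read(StringIO(nwk), "newick")
    assert {t.name for t in tree.get_terminals()} == {"a", "b", "c", "d"}


# ---------------------------------------------------------------- DML calling


def test_identical_profiles_not_called(design):
    m = _matrix([[20, 20, 20]] * 5, [[20, 20, 20]] * 5)
    assert len(call_dml(m, design, alpha=0.01)) == 0


def test_planted_direction_follows_inversion_rule(design):
    # hyper_in_TT: TT methylated -> TT counts ~0, OT counts high
    m = _matrix(
        [[0, 0, 0], [60, 55, 58]],
        [[60, 62, 58], [0, 1, 0]],
        index=["hyper", "hypo"],
    )
    dml = call_dml(m, design, alpha=0.01)
    assert dml.loc["hyper", "direction"] == "hyper_in_TT"
    assert dml.loc["hypo", "direction"] == "hypo_in_TT"
    assert dml.loc["hyper", "log2fc"] < 0 < dml.loc["hypo", "log2fc"]


def test_group_label_swap_mirrors_directions(design):
    rng = np.random.default_rng(11)
    tt, ot = rng.poisson(20, (40, 3)), rng.poisson(30, (40, 3))
    m = _matrix(tt, ot)
    swapped = _matrix(ot, tt)
    t1 = exact_test_table(m, design)
    t2 = exact_test_table(swapped, design)
    np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-9)
    flip = {"hypo_in_TT": "hyper_in_TT", "hyper_in_TT": "hypo_in_TT"}
    ties = t1["mean_count_tt"] == t1["mean_count_ot"]
    assert (t2["direction"][~ties] == t1["direction"][~ties].map(flip)).all()


def test_null_type_one_error_within_binomial_interval(design):
    rng = np.random.default_rng(12)
    n = 3000
    m = _matrix(rng.poisson(20, (n, 3)), rng.poisson(20, (n, 3)))
    table = exact_test_table(m, design, aggregate="sum")
    rate = (table["p"] < 0.01).mean()
    half = 1.96 * np.sqrt(0.01 * 0.99 / n)
    assert 0.01 - half <= rate <= 0.01 + half


def test_mean_aggregation_available(design):
    m = _matrix([[0, 0, 0]], [[60, 62, 58]])
    p_mean = exact_test_table(m, design, aggregate="mean")["p"].iloc[0]
    p_sum = exact_test_table(m, design, aggregate="sum")["p"].iloc[0]
    assert p_mean < 0.05 and p_sum < p_mean


def test_missing_group_raises():
    counts = pd.DataFrame({"TT1": [5], "TT2": [5], "TT3": [4]})
    cm = CountMatrix(counts, counts.sum() + 10, pd.Series(0, index=counts.columns))
    with pytest.raises(ValueError):
        exact_test_table(cm, StudyDesign())


# ---------------------------------------------------------------- summaries


def test_direction_summary_fractions():
    df = pd.DataFrame(
        {
            "context": ["CG"] * 5036,
            "direction": ["hypo_in_TT"] * 2367 + ["hyper_in_TT"] * 2669,
        }
    )
    out = direction_summary(df)
    hypo = out[(out["context"] == "CG") & (out["direction"] == "hypo_in_TT")]
    assert hypo["count"].iloc[0] == 2367
    assert hypo["percent"].iloc[0] == 47


def test_direction_summary_empty():
    out = direction_summary(pd.DataFrame(columns=["context", "direction"]))
    assert out.empty
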