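import numpy as np
import pandas as pd
import pytest

from methylrad.enzymes import revcomp
from methylrad.regulation import (
    ddct,
    network_stats,
    scan_targets,
    score_mirna_target,
)
from methylrad.stats import locus_ttest

MIRNA = "ACGTCGATCGGATCGTACGTA"  # 21 nt; G at positions 10, 11 and 15


def _perfect_target(mirna=MIRNA):
    return revcomp(mirna)


def _with_pair_change(mirna_pos, new_target_base, mirna=MIRNA):
    """Alter the target base pairing the given miRNA position (1-based)."""
    target = list(_perfect_target(mirna))
    # miRNA position i pairs target base at index L - i (antiparallel)
    target[len(mirna) - mirna_pos] = new_target_base
    return "".join(target)


def test_perfect_complement_scores_zero_cleavage():
    hit = score_mirna_target(MIRNA, _perfect_target())
    assert hit.expectation == 0.0
    assert hit.mode == "cleavage"
    assert hit.position == 0


def test_single_wobble_outside_core_scores_half():
    # miRNA position 15 is G; G:U wobble = target T instead of C
    assert MIRNA[14] == "G"
    hit = score_mirna_target(MIRNA, _with_pair_change(15, "T"))
    assert hit.expectation == pytest.approx(0.5)
    assert hit.mode == "cleavage"


def test_mismatch_at_position_ten_doubles_and_flags_inhibition():
    # position 10 pairs G (miRNA base G -> target C); make it A = mismatch
    assert MIRNA[9] == "G"
    hit = score_mirna_target(MIRNA, _with_pair_change(10, "A"))
    assert hit.expectation == pytest.approx(2.0)
    assert hit.mode == "translation_inhibition"


def test_wobble_at_position_eleven_flags_inhibition():
    assert MIRNA[10] == "G"
    hit = score_mirna_target(MIRNA, _with_pair_change(11, "T"))
    assert hit.expectation == pytest.approx(1.0)  # wobble doubled in core
    assert hit.mode == "translation_inhibition"


def test_score_monotone_in_mismatches():
    rng = np.random.default_rng(2)
    target = list(_perfect_target())
    last = 0.0
    positions = rng.permutation(np.arange(2, 8))  # core positions, +1.0*2 each
    for mirna_pos in positions[:3]:
        idx = len(MIRNA) - mirna_pos
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[target[idx]]
        # choose a base that is neither WC nor wobble for the miRNA base
        target[idx] = bad
        hit = score_mirna_target(MIRNA, "".join(target), max_expectation=100)
        assert hit.expectation > last
        last = hit.expectation


def test_expectation_threshold_suppresses_hit():
    target = list(_perfect_target())
    for idx in range(0, 6):
        target[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[target[idx]]
    assert score_mirna_target(MIRNA, "".join(target), max_expectation=5.0) is None


def test_best_window_found_in_longer_transcript():
    transcript = "A" * 37 + _perfect_target() + "C" * 11
    hit = score_mirna_target(MIRNA, transcript)
    assert hit.position == 37
    assert hit.expectation == 0.0


def test_rna_alphabet_accepted_and_invalid_rejected():
    rna = MIRNA.replace("T", "U")
    assert score_mirna_target(rna, _perfect_target()).expectation == 0.0
    with pytest.raises(ValueError):
        score_mirna_target(MIRNA.replace("G", "X", 1), _perfect_target())
    with pytest.raises(ValueError):
        score_mirna_target("ACGT", _perfect_target())  # too short


def test_scan_targets_table():
    hits = scan_targets(
        {"miR1": MIRNA}, {"t1": "AA" + _perfect_target() + "GG", "t2": "A" * 40}
    )
    assert list(hits["gene_id"]) == ["t1"]
    assert hits.iloc[0]["expectation"] == 0.0


# ---------------------------------------------------------------- network


def test_network_paper_scale_average_degree():
    # a simple graph with 205 nodes and 313 edges has average degree 3.05
    nodes = [f"n{i}" for i in range(205)]
    edges = [(nodes[i], nodes[(i + 1) % 205]) for i in range(205)]
    edges += [(nodes[i], nodes[(i + 7) % 205]) for i in range(108)]
    summary = network_stats(edges)
    assert (summary.n_nodes, summary.n_edges) == (205, 313)
    assert summary.average_degree == 3.05


def test_network_small_examples():
    assert network_stats([("a", "b")]) == (2, 1, 1.0)
    triangle = [("a", "b"), ("b", "c"), ("c", "a")]
    assert network_stats(triangle) == (3, 3, 2.0)


def test_network_self_loop_rejected_with_warning():
    with pytest.warns(UserWarning, match="self-loop"):
        summary = network_stats([("a", "a"), ("a", "b")])
    assert (summary.n_nodes, summary.n_edges) == (2, 1)


def test_network_average_degree_equals_mean_node_degree():
    import networkx as nx

    rng = np.random.default_rng(3)
    edges = {tuple(sorted(rng.choice(20, 2, replace=False))) for _ in range(40)}
    edges = [(f"n{a}", f"n{b}") for a, b in edges]
    summary = network_stats(edges)
    g = nx.Graph(edges)
    assert summary.average_degree == pytest.approx(
        np.mean([d for _, d in g.degree()]), abs=0.005
    )


# ---------------------------------------------------------------- ddCT


def _ct_records(target_ct_tt, target_ct_ot, ref1=20.0, ref2=22.0):
    rows = []
    for group, cts in (("true_to_type", target_ct_tt), ("off_type", target_ct_ot)):
        for i, ct in enumerate(cts):
            sample = f"{group[:2].upper()}{i + 1}"
            for assay, value in (("GENE1", ct), ("ACT", ref1), ("EF1", ref2)):
                for rep in range(3):  # technical replicates
                    rows.append(
                        {"gene": "GENE1", "sample": sample, "group": group,
                         "assay": assay, "replicate": rep, "ct": value}
                    )
    return pd.DataFrame(rows)


def test_identical_cts_give_fold_change_one():
    res = ddct(_ct_records([24, 24, 24], [24, 24, 24]))
    assert np.allclose(res.per_sample["fold_change"], 1.0)
    assert res.per_gene.iloc[0]["fold_change_vs_calibrator"] == pytest.approx(1.0)


def test_hand_computed_ddct_example():
    # sample target CT 25 vs calibrator 24, refs 20 and 22 everywhere:
    # dCT = 25-21 = 4 vs 3 -> ddCT = 1 -> fold change 0.5 (down-expressed)
    res = ddct(_ct_records([24, 24, 24], [25, 25, 25]))
    ot = res.per_sample[res.per_sample["group"] == "off_type"]
    assert np.allclose(ot["ddct"], 1.0)
    assert np.allclose(ot["fold_change"], 0.5)
    assert res.per_gene.iloc[0]["regulation"] == "down"


def test_calibrator_group_mean_fold_change_is_one():
    res = ddct(_ct_records([23.8, 24.1, 24.4], [26, 25, 27]))
    calib = res.per_sample[res.per_sample["group"] == "true_to_type"]
    assert calib["ddct"].mean() == pytest.approx(0.0, abs=1e-12)
    assert 2 ** (-calib["ddct"].mean()) == pytest.approx(1.0)


def test_group_pvalue_uses_shared_ttest():
    records = _ct_records([24.0, 24.3, 23.9], [25.2, 25.6, 25.1])
    res = ddct(records)
    tt_dct = [24.0 - 21, 24.3 - 21, 23.9 - 21]
    ot_dct = [25.2 - 21, 25.6 - 21, 25.1 - 21]
    expected = locus_ttest(tt_dct, ot_dct)
    assert res.per_gene.iloc[0]["p"] == pytest.approx(expected.p)
    assert res.per_gene.iloc[0]["t"] == pytest.approx(expected.t)


def test_missing_reference_assay_skips_record_with_warning():
    records = _ct_records([24, 24, 24], [25, 25, 25])
    records = records[~((records["sample"] == "TR1") & (records["assay"] == "EF1"))]
    with pytest.warns(UserWarning, match="missing reference"):
        res = ddct(records)
    assert "TR1" not in set(res.per_sample["sample"])


def test_positive_ct_required():
    records = _ct_records([24, 24, 24], [25, 25, 25])
    records.loc[0, "ct"] = -1.0
    with pytest.raises(ValueError):
        ddct(records)
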