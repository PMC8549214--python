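"""Hypergeometric ORA, kappa clustering and cross-view consistency."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zhengomics.enrich import (
    cluster_terms,
    cross_view_consistency,
    joint_ora,
    kappa_matrix,
    ora,
    percentage,
)


# -- ORA ---------------------------------------------------------------------

def test_ora_exact_tail_sum():
    """N=20, K=5, n=5, k=3: p = [C(5,3)C(15,2)+C(5,4)C(15,1)+C(5,5)]/C(20,5)."""
    universe = {f"u{i}" for i in range(20)}
    members = {f"u{i}" for i in range(5)}
    query = {"u0", "u1", "u2", "u10", "u11"}
    out = ora(query, {"T": members}, universe)
    expected = (math.comb(5, 3) * math.comb(15, 2)
                + math.comb(5, 4) * math.comb(15, 1)
                + math.comb(5, 5)) / math.comb(20, 5)
    assert out.loc[0, "p"] == pytest.approx(expected)
    assert out.loc[0, "k"] == 3


def test_ora_zero_overlap_gives_p_one():
    universe = {f"u{i}" for i in range(10)}
    out = ora({"u0"}, {"T": {"u5", "u6"}}, universe)
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_ora_query_equals_universe_gives_p_one():
    universe = {f"u{i}" for i in range(6)}
    out = ora(universe, {"T": universe}, universe)
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_ora_empty_effective_query_errors():
    with pytest.raises(ValueError):
        ora({"absent"}, {"T": {"u1"}}, {"u1", "u2"})


def test_ora_matches_fisher_exact():
    """Upper-tail hypergeometric equals one-sided Fisher on the 2x2 table."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        N = int(rng.integers(10, 60))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        universe = [f"u{i}" for i in range(N)]
        members = set(rng.choice(universe, size=K, replace=False))
        query = set(rng.choice(universe, size=n, replace=False))
        k = len(members & query)
        out = ora(query, {"T": members}, set(universe))
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert out.loc[0, "p"] == pytest.approx(p_fisher, rel=1e-9)


def test_ora_invariant_to_input_order():
    universe = {f"u{i}" for i in range(30)}
    sets = {f"T{j}": {f"u{i}" for i in range(j, j + 8)} for j in range(5)}
    q = {"u1", "u3", "u5", "u7"}
    a = ora(q, sets, universe)
    b = ora(set(reversed(sorted(q))), dict(reversed(list(sets.items()))), universe)
    pd.testing.assert_frame_equal(a, b)


def test_bh_q_monotone_in_p_rank():
    universe = {f"u{i}" for i in range(50)}
    rng = np.random.default_rng(1)
    sets = {f"T{j}": set(rng.choice(sorted(universe), size=10, replace=False))
            for j in range(8)}
    out = ora({"u0", "u1", "u2", "u3", "u4"}, sets, universe)
    q_sorted = out.sort_values("p")["q"].to_numpy()
    assert (np.diff(q_sorted) >= -1e-12).all()


# -- joint ORA ---------------------------------------------------------------

def test_joint_query_namespace_collision():
    with pytest.raises(ValueError):
        joint_ora({"x"}, {"x"}, {"T": {"x"}}, {"x"})


def test_joint_gene_only_term_with_metabolite_query():
    universe = {"g1", "g2", "m1", "m2"}
    out = joint_ora(set(), {"m1"}, {"T": {"g1", "g2"}}, universe)
    assert out.loc[0, "k"] == 0
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_joint_reduces_to_flat_ora():
    universe = {"g1", "g2", "g3", "m1", "m2", "m3"}
    term = {"g1", "m1", "m2"}
    a = joint_ora({"g1"}, {"m1", "m2"}, {"T": term}, universe)
    b = ora({"g1", "m1", "m2"}, {"T": term}, universe)
    pd.testing.assert_frame_equal(a, b)


def test_joint_constructed_tail():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(15)]
    mets = [f"m{i}" for i in range(15)]
    universe = set(genes) | set(mets)
    term = set(genes[:3]) | set(mets[:3])
    query = set(genes[:2]) | set(mets[:2]) | {"g9", "m9"}
    out = joint_ora(set(genes[:2]) | {"g9"}, set(mets[:2]) | {"m9"}, {"T": term}, universe)
    # brute-force hypergeometric tail: N=30, K=6, n=6, k=4
    expected = sum(
        math.comb(6, k) * math.comb(24, 6 - k) for k in range(4, 7)
    ) / math.comb(30, 6)
    assert out.loc[0, "k"] == 4
    assert out.loc[0, "p"] == pytest.approx(expected)


# -- percentage --------------------------------------------------------------

@pytest.mark.parametrize("k, n, expected", [(5, 24, 20.83), (5, 23, 21.74), (0, 7, 0.0)])
def test_report_percentage(k, n, expected):
    assert percentage(k, n) == expected


def test_percentage_errors():
    with pytest.raises(ValueError):
        percentage(1, 0)
    with pytest.raises(ValueError):
        percentage(5, 4)


# -- kappa -------------------------------------------------------------------

def test_kappa_identical_profiles():
    items = {"a", "b", "c", "d"}
    kap = kappa_matrix(items, {"T1": {"a", "b"}, "T2": {"a", "b"}})
    assert kap.loc["T1", "T2"] == pytest.approx(1.0)


def test_kappa_complementary_profiles():
    items = {"a", "b", "c", "d"}
    kap = kappa_matrix(items, {"T1": {"a", "b"}, "T2": {"c", "d"}})
    assert kap.loc["T1", "T2"] == pytest.approx(-1.0)


def test_kappa_independent_profiles():
    items = {"a", "b", "c", "d"}
    kap = kappa_matrix(items, {"T1": {"a", "b"}, "T2": {"a", "c"}})
    assert kap.loc["T1", "T2"] == pytest.approx(0.0)


def test_kappa_degenerate_pair_is_zero():
    items = {"a", "b"}
    kap = kappa_matrix(items, {"T1": {"a", "b"}, "T2": {"a", "b", "c"}})
    # both annotate every item: expected agreement 1 -> defined as 0
    assert kap.loc["T1", "T2"] == 0.0


# -- clustering --------------------------------------------------------------

def _rows(pvals):
    return pd.DataFrame({"term": list(pvals), "p": list(pvals.values())})


def test_singleton_cluster_score_is_neg_log10_p():
    items = {f"i{j}" for j in range(6)}
    sets = {"T1": {"i0", "i1"}, "T2": {"i4", "i5"}}
    kap = kappa_matrix(items, sets)
    clusters = cluster_terms(_rows({"T1": 1e-4, "T2": 1e-2}), kap, "high")
    scores = {c.members[0]: c.score for c in clusters if len(c.members) == 1}
    assert scores["T1"] == pytest.approx(4.0)
    assert scores["T2"] == pytest.approx(2.0)


def test_cluster_score_geometric_mean():
    """Members with p {1e-4, 1e-2} give -log10(gmean) = 3.0."""
    items = {f"i{j}" for j in range(4)}
    sets = {"T1": {"i0", "i1"}, "T2": {"i0", "i1"}, "T3": {"i0", "i1"},
            "T4": {"i0", "i1"}}
    kap = kappa_matrix(items, sets)
    clusters = cluster_terms(
        _rows({"T1": 1e-4, "T2": 1e-2, "T3": 1e-4, "T4": 1e-2}), kap, "high"
    )
    assert len(clusters) == 1
    assert clusters[0].score == pytest.approx(3.0)
    assert clusters[0].rank == 1


def test_two_kappa_blocks_give_two_clusters():
    items = {f"i{j}" for j in range(8)}
    block1 = {"i0", "i1", "i2", "i3"}
    block2 = {"i4", "i5", "i6", "i7"}
    sets = {f"A{j}": block1 for j in range(4)} | {f"B{j}": block2 for j in range(4)}
    kap = kappa_matrix(items, sets)
    clusters = cluster_terms(_rows({t: 0.01 for t in sets}), kap, "high")
    assert len(clusters) == 2
    assert {frozenset(c.members) for c in clusters} == {
        frozenset({"A0", "A1", "A2", "A3"}),
        frozenset({"B0", "B1", "B2", "B3"}),
    }


# -- cross-view consistency --------------------------------------------------

def test_consistency_flags():
    hits = {
        "CCQS": {
            "proteomics": {"P1", "P2"},
            "metabolomics": {"P1"},
            "integrated": {"P1", "P3"},
        },
        "QSBS": {
            "proteomics": {"P2"},
            "metabolomics": set(),
            "integrated": set(),
        },
    }
    table = cross_view_consistency(hits)
    by = {(r["syndrome"], r["term"]): r for r in table.to_dict(orient="records")}
    assert by[("CCQS", "P1")]["flag"] == "consistent"
    assert by[("CCQS", "P3")]["flag"] == "integrated-only"
    assert by[("CCQS", "P2")]["flag"] == "proteomics-only"
    assert by[("CCQS", "P2")]["shared_between_syndromes"]
    assert not by[("CCQS", "P1")]["shared_between_syndromes"]
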