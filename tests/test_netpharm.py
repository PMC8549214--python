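"""Active-compound filtering, signatures, disease similarity, drug overlap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zhengomics.netpharm import (
    CompoundRecord,
    DiseaseRecord,
    DrugRecord,
    FormulaDef,
    assign_atc_categories,
    disease_similarity,
    filter_active,
    formula_targets,
    jaccard,
    map_drug_overlap,
    signature_targets,
    specific_signatures,
)


def rec(cid, source, **kw):
    return CompoundRecord(cid, kw.pop("herb", "H01"), source, **kw)


# -- activity filter ---------------------------------------------------------

@pytest.mark.parametrize(
    "record, kept",
    [
        (rec("c1", "tcmsp", ob=30.0, dl=0.18), True),    # inclusive boundary
        (rec("c2", "tcmsp", ob=29.9, dl=0.5), False),
        (rec("c3", "tcmsp", ob=50.0, dl=0.179), False),
        (rec("c4", "etcm", grading="good"), True),
        (rec("c5", "etcm", grading="moderate"), True),
        (rec("c6", "etcm", grading="weak"), False),
        (rec("c7", "qmarker"), True),                     # no attributes needed
        (rec("c8", "tcmsp"), False),                      # missing OB/DL -> rejected
    ],
)
def test_activity_rules(record, kept):
    assert (record in filter_active([record])) == kept


def test_filter_active_idempotent():
    records = [rec(f"c{i}", "tcmsp", ob=float(20 + i * 5), dl=0.1 + i * 0.05)
               for i in range(6)]
    once = filter_active(records)
    assert filter_active(once) == once


# -- formula targets ---------------------------------------------------------

def test_formula_targets_union_and_bookkeeping():
    f = FormulaDef("F1-1", ("H01",), "CCQS")
    active = [
        rec("c1", "qmarker", targets=frozenset({"a", "b"})),
        rec("c2", "qmarker", targets=frozenset({"b", "c"})),
        rec("c3", "qmarker", targets=frozenset()),
        rec("c4", "qmarker", herb="H99", targets=frozenset({"z"})),  # other herb
    ]
    ft = formula_targets(f, active)
    assert ft.targets == {"a", "b", "c"}
    assert ft.n_active == 3
    assert ft.n_active_with_targets == 2
    assert ft.n_targets == 3


def test_duplicate_compound_across_sources_unions_targets():
    f = FormulaDef("F1-1", ("H01",), "CCQS")
    active = [
        rec("c1", "tcmsp", ob=40.0, dl=0.3, targets=frozenset({"a"})),
        rec("c1", "etcm", grading="good", targets=frozenset({"b"})),
    ]
    ft = formula_targets(f, filter_active(active))
    assert ft.n_active == 1
    assert ft.targets == {"a", "b"}


def test_synthetic_kb_counts_match_ground_truth(knowledgebase_run):
    kb, gt = knowledgebase_run
    active = filter_active(kb.compounds)
    for f in kb.formulae:
        assert formula_targets(f, active).targets == gt.formula_targets[f.code]


# -- signatures --------------------------------------------------------------

def test_signature_triple_intersection():
    assert signature_targets({"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}) == {"c"}
    assert signature_targets(set(), {"a"}, {"a"}) == set()


def test_pairwise_nonempty_triple_empty():
    t1, t2, t3 = {"a", "b"}, {"b", "c"}, {"c", "a"}
    assert t1 & t2 and t2 & t3 and t1 & t3
    assert signature_targets(t1, t2, t3) == set()


def test_specific_signature_partition_sizes():
    common = {f"x{i}" for i in range(182)}
    f1 = common | {f"a{i}" for i in range(70)}
    f2 = common | {f"b{i}" for i in range(36)}
    c, only1, only2 = specific_signatures(f1, f2)
    assert (len(c), len(only1), len(only2)) == (182, 70, 36)
    assert c | only1 | only2 == f1 | f2
    assert not (only1 & only2 or c & only1 or c & only2)


def test_signature_subset_of_inputs(knowledgebase_run):
    kb, gt = knowledgebase_run
    active = filter_active(kb.compounds)
    t = [formula_targets(f, active).targets for f in kb.formulae if f.syndrome == "CCQS"]
    sig = signature_targets(*t)
    for ts in t:
        assert sig <= ts


# -- Jaccard / disease similarity -------------------------------------------

def test_jaccard_known_values():
    assert jaccard({"a"}, {"a"}) == 1.0
    assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
    assert jaccard(set(), set()) == 0.0


@settings(max_examples=50, deadline=None)
@given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
def test_jaccard_symmetric_and_bounded(a, b):
    j = jaccard(a, b)
    assert 0.0 <= j <= 1.0
    assert j == jaccard(b, a)
    assert (j == 1.0) == (a == b and len(a) > 0)


def test_disease_thresholds_are_strict():
    # JIg exactly 0.2: 1 shared / 5 union
    query = DiseaseRecord("q", frozenset("abc"), frozenset("xy"))
    boundary = DiseaseRecord("d", frozenset({"a", "p", "q"}), frozenset({"x"}))
    assert jaccard(query.genes, boundary.genes) == pytest.approx(0.2)
    out = disease_similarity(query, [boundary], jig_thresh=0.2, jiv_thresh=0.05)
    assert not out["related"].iloc[0]


def test_related_disease_detection(knowledgebase_run):
    kb, gt = knowledgebase_run
    out = disease_similarity(kb.chd, kb.diseases)
    found = set(out.loc[out["related"], "disease"])
    assert found == gt.related_diseases


# -- drug overlap ------------------------------------------------------------

def test_atc_longest_prefix_assignment():
    drug = DrugRecord("d1", ("A10BA02",), frozenset())
    assert assign_atc_categories(drug, ["A10", "A08", "C", "B01"]) == {"A10"}
    # 'A' alone would shadow A10 unless the longest match wins
    assert assign_atc_categories(drug, ["A", "A10"]) == {"A10"}
    none = DrugRecord("d2", ("N05AH04",), frozenset())
    assert assign_atc_categories(none, ["A10", "C"]) == set()


def test_drug_overlap_counts_and_edges():
    partitions = {"p1": {"x", "y"}}
    drugs = [DrugRecord("d1", ("C01AA05",), frozenset({"y", "z"}))]
    counts, net = map_drug_overlap(partitions, drugs, ("C", "A10"))
    assert counts.loc["p1", "C"] == 1
    assert counts.loc["p1", "A10"] == 0
    assert net.has_edge("y", "d1")
    assert net.number_of_edges() == 1


def test_category_partition_coupling(knowledgebase_run):
    """The generator couples A10 drugs to the CCQS core and A08/B01 to QSBS."""
    kb, gt = knowledgebase_run
    partitions = {"ccqs_core": gt.signature_core["CCQS"],
                  "qsbs_core": gt.signature_core["QSBS"]}
    counts, _ = map_drug_overlap(partitions, kb.drugs)
    assert counts.loc["ccqs_core", "A10"] > 0
    assert counts.loc["qsbs_core", "B01"] > 0
    assert counts.loc["ccqs_core", "A08"] == 0
    assert counts.loc["qsbs_core", "A10"] == 0
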