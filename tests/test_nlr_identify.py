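import itertools

import pytest
from hypothesis import given, settings, strategies as st

from nlrevo import (NLRClass, ReferenceLabel, classify_architecture,
                    drop_redundant_isoforms, filter_by_phylogeny,
                    merge_candidates)
from .conftest import arch_from_flags

# Exhaustive expected classification for every 2^5 presence combination,
# frozen from the stated rules: NB-ARC gates NLR status; precedence
# TIR > RPW8 > Rx_N; LRR never changes the class.
TRUTH_TABLE = {}
for nbarc, tir, rpw8, rxn, lrr in itertools.product([False, True], repeat=5):
    if not nbarc:
        expected = "NOT_NLR"
    elif tir:
        expected = "TNL"
    elif rpw8:
        expected = "RNL"
    elif rxn:
        expected = "CNL"
    else:
        expected = "NL"
    TRUTH_TABLE[(nbarc, tir, rpw8, rxn, lrr)] = expected


@pytest.mark.parametrize("flags,expected", [
    (dict(nbarc=True, tir=True, lrr=True), NLRClass.TNL),
    (dict(nbarc=True, rxn=True, lrr=True), NLRClass.CNL),
    (dict(nbarc=True, rpw8=True), NLRClass.RNL),
    (dict(nbarc=True), NLRClass.NL),
    (dict(nbarc=True, lrr=True), NLRClass.NL),
    (dict(lrr=True), NLRClass.NOT_NLR),
    (dict(nbarc=True, tir=True, rxn=True), NLRClass.TNL),  # TIR precedence
])
def test_classify_architecture_examples(flags, expected):
    assert classify_architecture(arch_from_flags(**flags)) is expected


def test_classification_matches_exhaustive_truth_table():
    for (nbarc, tir, rpw8, rxn, lrr), expected in TRUTH_TABLE.items():
        arch = arch_from_flags(nbarc, tir, rpw8, rxn, lrr)
        assert classify_architecture(arch).value == expected


def test_classification_is_a_partition():
    archs = [arch_from_flags(*combo) for combo in TRUTH_TABLE]
    labels = [classify_architecture(a) for a in archs]
    counts = {c: labels.count(c) for c in NLRClass}
    assert sum(counts.values()) == len(archs)


def test_multi_nterminal_flag():
    assert arch_from_flags(nbarc=True, tir=True, rxn=True).is_multi_nterminal
    assert not arch_from_flags(nbarc=True, tir=True).is_multi_nterminal


def test_merge_candidates_examples():
    assert merge_candidates({"x", "y"}, {"y", "z"}) == {"x", "y", "z"}
    assert merge_candidates(set(), set()) == set()


@settings(max_examples=50, derandomize=True)
@given(a=st.sets(st.text("abc", min_size=1, max_size=3), max_size=100),
       b=st.sets(st.text("abc", min_size=1, max_size=3), max_size=100))
def test_merge_candidates_set_semantics(a, b):
    assert merge_candidates(a, b) == a | b  # set-union oracle
    assert merge_candidates(a, b) == merge_candidates(b, a)
    assert merge_candidates(a, a) == a
    assert merge_candidates(merge_candidates(a, b), b) == a | b


def _labels(**kv):
    return [ReferenceLabel(k, v) for k, v in kv.items()]


def test_filter_by_phylogeny_rules(labeled_tree):
    t = labeled_tree("((cand1,plantR1),nonplant1);", None)
    assert filter_by_phylogeny(
        t, _labels(cand1="candidate", plantR1="plant_R",
                   nonplant1="non_plant")) == {"cand1"}
    t2 = labeled_tree("((cand1,nonplant1),plantR1);", None)
    assert filter_by_phylogeny(
        t2, _labels(cand1="candidate", nonplant1="non_plant",
                    plantR1="plant_R")) == set()
    # nearest-reference clade mixes both kinds -> excluded under strict
    t3 = labeled_tree("((cand1,(plantR1,nonplant1)),plantR2);", None)
    labs = _labels(cand1="candidate", plantR1="plant_R",
                   nonplant1="non_plant", plantR2="plant_R")
    assert filter_by_phylogeny(t3, labs, "strict") == set()


def test_filter_by_phylogeny_reference_extremes(labeled_tree):
    only_plant = labeled_tree("((c1,p1),(c2,p2));", None)
    labs = _labels(c1="candidate", c2="candidate", p1="plant_R", p2="plant_R")
    assert filter_by_phylogeny(only_plant, labs) == {"c1", "c2"}
    only_non = labeled_tree("((c1,n1),(c2,n2));", None)
    labs = _labels(c1="candidate", c2="candidate", n1="non_plant", n2="non_plant")
    assert filter_by_phylogeny(only_non, labs) == set()


def test_filter_by_phylogeny_permissive_mode(labeled_tree):
    # candidate's nearest-reference clade mixes, but a pure plant_R+candidate
    # clade exists below it on the other branch only in permissive reading
    t = labeled_tree("(((cand1,plantR1),nonplant1),outg1);", None)
    labs = _labels(cand1="candidate", plantR1="plant_R",
                   nonplant1="non_plant", outg1="outgroup")
    assert filter_by_phylogeny(t, labs, "strict") == {"cand1"}
    assert filter_by_phylogeny(t, labs, "permissive") == {"cand1"}


def test_filter_by_phylogeny_errors(labeled_tree):
    t = labeled_tree("((c1,p1),n1);", None)
    with pytest.raises(ValueError, match="label"):
        filter_by_phylogeny(t, _labels(c1="candidate", p1="plant_R"))
    t2 = labeled_tree("(c1,o1);", None)
    with pytest.raises(ValueError, match="reference"):
        filter_by_phylogeny(t2, _labels(c1="candidate", o1="outgroup"))


def test_drop_redundant_isoforms():
    assert drop_redundant_isoforms(
        [("p1.a", "L1", 300), ("p1.b", "L1", 450)]) == {"p1.b"}
    assert drop_redundant_isoforms(
        [("a", "L1", 10), ("b", "L2", 20)]) == {"a", "b"}
    assert drop_redundant_isoforms(
        [("pB", "L1", 400), ("pA", "L1", 400)]) == {"pA"}  # lexicographic tie
    with pytest.raises(ValueError, match="negative"):
        drop_redundant_isoforms([("p", "L", -1)])
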