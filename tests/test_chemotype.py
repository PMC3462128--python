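"""Chemotype rule engine: table analytics, signatures, votes, predictions."""

from collections import Counter
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2pks.chemotype import (
    ChemotypeRule,
    RuleTable,
    UNCLASSIFIED,
    count_unique,
    homolog_vote,
    overlapping_pairs,
    predict_chemotype,
    signature,
)
from t2pks.classifiers import DomainCall
from t2pks.io_formats import GeneRecord, ReferenceDomain
from t2pks.mining import PksCluster

ALL_KEYS = [("ARO", s) for s in "abc"] + [("CYC", s) for s in "abcdef"]


def _cluster(call_keys, valid=True, seqs=None):
    genes = []
    for i, key in enumerate(call_keys):
        seq = seqs[i] if seqs else "MKTAYIAKQRQISFVKSHFSRQ"
        gene = GeneRecord(f"g{i}", seq, start=1 + i * 3000, end=2000 + i * 3000)
        genes.append((gene, [DomainCall(gene.gene_id, key, 50.0, "HMM")]))
    return PksCluster("c1", "G1", genes, valid=valid)


# ---------------------------------------------------------------------------
# Rule table analytics
# ---------------------------------------------------------------------------

def test_embedded_table_shape_and_examples(rule_table):
    assert len(rule_table.rules) == 11
    ang = [r for r in rule_table.rules if r.chemotype == "Angucyclines"]
    assert len(ang) == 1
    assert ang[0].combination == frozenset(
        {("ARO", "a"), ("ARO", "b"), ("CYC", "a")}
    )
    assert ang[0].unique
    shared = frozenset({("ARO", "c"), ("CYC", "a"), ("CYC", "b")})
    sharing = {r.chemotype for r in rule_table.rules if r.combination == shared}
    assert sharing == {"PentangularPolyphenols", "Tetracenomycins"}
    assert all(not r.unique for r in rule_table.rules if r.combination == shared)


def test_count_unique_on_printed_table(rule_table):
    assert count_unique(rule_table) == 7


def test_count_unique_trivial_tables():
    distinct = RuleTable(
        [
            ChemotypeRule("A", frozenset({("ARO", "a")}), True),
            ChemotypeRule("B", frozenset({("ARO", "b")}), True),
        ]
    )
    assert count_unique(distinct) == 2
    duplicated = RuleTable(
        [
            ChemotypeRule("A", frozenset({("ARO", "a")}), False),
            ChemotypeRule("B", frozenset({("ARO", "a")}), False),
        ]
    )
    assert count_unique(duplicated) == 0


def test_overlapping_pairs_printed_and_oracle(rule_table):
    pairs = overlapping_pairs(rule_table)
    assert pairs == {
        ("Anthracyclines", "Tetracyclines/AureolicAcids"),
        ("PentangularPolyphenols", "Tetracenomycins"),
    }
    # O(n^2) brute force over rule pairs
    oracle = set()
    for a, b in combinations(rule_table.rules, 2):
        if a.combination == b.combination and a.chemotype != b.chemotype:
            oracle.add(tuple(sorted((a.chemotype, b.chemotype))))
    assert pairs == oracle
    assert count_unique(rule_table) + 4 == len(rule_table.rules)


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

def test_signature_projects_to_aro_cyc_only():
    cluster = _cluster(
        [("KS", "a"), ("CLF", "a"), ("ACP", "a"), ("ARO", "a"), ("ARO", "b"), ("CYC", "a")]
    )
    assert signature(cluster) == frozenset(
        {("ARO", "a"), ("ARO", "b"), ("CYC", "a")}
    )


def test_signature_empty_and_set_semantics():
    assert signature(_cluster([("KS", "a"), ("CLF", "a")])) == frozenset()
    dup = _cluster([("ARO", "a"), ("ARO", "a"), ("KS", "a"), ("CLF", "a")])
    assert signature(dup) == frozenset({("ARO", "a")})


# ---------------------------------------------------------------------------
# Prediction paths
# ---------------------------------------------------------------------------

def test_unique_combination_assigned_directly(rule_table):
    cluster = _cluster([("KS", "a"), ("CLF", "a"), ("ARO", "a"), ("ARO", "b"), ("CYC", "a")])
    pred = predict_chemotype(cluster, rule_table)
    assert pred.chemotype == "Angucyclines"
    assert pred.rule_path == "unique_match"


def test_overlapped_combination_resolved_by_vote(rule_table):
    cluster = _cluster([("KS", "a"), ("CLF", "a"), ("ARO", "c"), ("CYC", "a"), ("CYC", "b")])
    votes = Counter({"Tetracenomycins": 9, "PentangularPolyphenols": 4})
    pred = predict_chemotype(cluster, rule_table, votes=votes)
    assert pred.chemotype == "Tetracenomycins"
    assert pred.rule_path == "homolog_vote"
    assert not pred.ambiguous


def test_vote_tie_reported_ambiguous(rule_table):
    cluster = _cluster([("KS", "a"), ("CLF", "a"), ("ARO", "c"), ("CYC", "a"), ("CYC", "b")])
    votes = Counter({"Tetracenomycins": 5, "PentangularPolyphenols": 5})
    pred = predict_chemotype(cluster, rule_table, votes=votes)
    assert pred.ambiguous
    assert pred.chemotype in votes


def test_incomplete_composition_unclassified(rule_table):
    pred = predict_chemotype(_cluster([("KS", "a"), ("CLF", "a")]), rule_table)
    assert pred.chemotype == UNCLASSIFIED and pred.rule_path == "unclassified"


def test_invalid_cluster_rejected(rule_table):
    with pytest.raises(ValueError):
        predict_chemotype(_cluster([("ARO", "a")], valid=False), rule_table)


def test_prediction_pure_in_gene_order(rule_table):
    keys = [("KS", "a"), ("CLF", "a"), ("ARO", "a"), ("ARO", "b"), ("CYC", "a")]
    a = predict_chemotype(_cluster(keys), rule_table)
    b = predict_chemotype(_cluster(list(reversed(keys))), rule_table)
    assert (a.chemotype, a.rule_path) == (b.chemotype, b.rule_path)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.sets(st.sampled_from(ALL_KEYS), min_size=0, max_size=6))
def test_exact_set_matching_property(keys):
    """Signatures matching no combination exactly are Unclassified —
    supersets and subsets of a rule do not match in strict mode."""
    from t2pks.chemotype import load_rule_table

    rt = load_rule_table()
    sig = frozenset(keys)
    cluster = _cluster([("KS", "a"), ("CLF", "a")] + sorted(sig))
    pred = predict_chemotype(cluster, rt, votes=Counter({"X": 1}))
    combos = {r.combination for r in rt.rules}
    if sig not in combos:
        assert pred.chemotype == UNCLASSIFIED
    else:
        assert pred.chemotype != UNCLASSIFIED


# ---------------------------------------------------------------------------
# Homolog votes against the reference set
# ---------------------------------------------------------------------------

def test_self_homology_vote_is_unanimous(refset, rule_table):
    """A cluster whose ARO c domain is a verbatim reference member of a
    pentangular-polyphenol source tallies only labels of ARO c members."""
    member = next(
        d for d in refset.domains
        if d.subfamily_key == ("ARO", "c") and d.chemotype == "PentangularPolyphenols"
    )
    cluster = _cluster([("ARO", "c")], seqs=[member.sequence])
    tally = homolog_vote(cluster, refset.domains)
    census = refset.chemotype_census([("ARO", "c")])
    assert tally == Counter(census)
    assert tally.most_common(1)[0][0] == "PentangularPolyphenols"


def test_vote_majority_from_constructed_split():
    """60/40 homolog label split returns the majority with both counts."""
    from t2pks.synthetic import FamilySpec, generate_family

    fam = generate_family(FamilySpec(120, 10, 0.03, 0.0, seed=55))
    labels = ["A"] * 6 + ["B"] * 4
    reference = [
        ReferenceDomain(f"r{i}", s, "CYC", "a", chemotype=l)
        for i, (s, l) in enumerate(zip(fam.members, labels))
    ]
    cluster = _cluster([("CYC", "a")], seqs=[fam.members[0]])
    tally = homolog_vote(cluster, reference)
    assert tally == Counter({"A": 6, "B": 4})


def test_no_homologs_empty_tally(rule_table):
    reference = [
        ReferenceDomain("r0", "WWWWWWWWWWCCCCCCCCCC", "CYC", "a", chemotype="A")
    ]
    cluster = _cluster([("ARO", "c"), ("CYC", "a"), ("CYC", "b")], seqs=None)
    tally = homolog_vote(cluster, reference)
    assert tally == Counter()
    cluster2 = _cluster(
        [("KS", "a"), ("CLF", "a"), ("ARO", "c"), ("CYC", "a"), ("CYC", "b")]
    )
    pred = predict_chemotype(cluster2, rule_table, reference=reference)
    assert pred.chemotype == UNCLASSIFIED
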