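"""Domain classifiers: metrics, profiles, SVMs, CV protocol, call policy."""

import math

import numpy as np
import pytest

from t2pks.classifiers import (
    ConfusionCounts,
    ModelBank,
    _split_protocol,
    build_msa,
    build_profile,
    compute_metrics,
    cross_validate,
    feature_vector,
    gappy_columns,
    label_permutation_mcc,
    train_svm,
)
from t2pks.synthetic import FamilySpec, generate_family, generate_negatives

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics_oracle(tp, tn, fp, fn):
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ac = (tp + tn) / (tp + tn + fp + fn)
    den = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(den) if den else 0.0
    return 100 * sn, 100 * sp, 100 * ac, 100 * mcc


def test_perfect_classifier_row():
    """An all-correct confusion of 43+43 gives 100/100/100/100."""
    m = compute_metrics(ConfusionCounts(43, 43, 0, 0))
    assert (m.SN, m.SP, m.AC, m.MCC) == (100.0, 100.0, 100.0, 100.0)


def test_chance_level_case():
    m = compute_metrics(ConfusionCounts(1, 1, 1, 1))
    assert m.AC == 50.0 and m.MCC == 0.0


def test_metrics_match_arithmetic_oracle_on_random_tables():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        tp, tn, fp, fn = (int(x) for x in rng.integers(0, 200, size=4))
        if tp + tn + fp + fn == 0:
            continue
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        for got, want in zip((m.SN, m.SP, m.AC, m.MCC), metrics_oracle(tp, tn, fp, fn)):
            assert got == pytest.approx(want, abs=1e-9)


def test_metrics_reject_all_zero_and_negative():
    with pytest.raises(ValueError):
        compute_metrics(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# MSA + profile HMM
# ---------------------------------------------------------------------------

def test_msa_of_identical_sequences_is_gap_free():
    msa = build_msa(["MKTAYIAK"] * 2)
    assert msa == ["MKTAYIAK", "MKTAYIAK"]


def test_msa_length_at_least_longest_member():
    fam = generate_family(FamilySpec(80, 6, 0.10, 0.01, seed=2))
    msa = build_msa(fam.members)
    assert len({len(r) for r in msa}) == 1
    assert len(msa[0]) >= max(len(m) for m in fam.members)


def test_gappy_columns_counted_by_direct_scan():
    msa = ["AC-E", "A--E", "ACDE"]
    flagged = gappy_columns(msa, max_gap_frac=0.5)
    direct = [
        j
        for j in range(4)
        if sum(r[j] == "-" for r in msa) / 3 > 0.5
    ]
    assert flagged == direct == [2]


@pytest.fixture(scope="module")
def family_and_profile():
    fam = generate_family(FamilySpec(150, 12, 0.08, 0.0, seed=21))
    model = build_profile(build_msa(fam.members), ("KS", "a"), members=fam.members)
    return fam, model


def test_training_members_score_above_threshold(family_and_profile):
    fam, model = family_and_profile
    for m in fam.members:
        res = model.score(m)
        assert res is not None and res[0] >= model.threshold


def test_shuffled_decoys_score_below_threshold(family_and_profile):
    """100 residue shuffles of a member never reach the calibrated threshold."""
    fam, model = family_and_profile
    rng = np.random.default_rng(5)
    for _ in range(100):
        decoy = "".join(rng.permutation(list(fam.members[0])))
        res = model.score(decoy)
        assert res is None or res[0] < model.threshold


def test_cross_family_rejection(family_and_profile):
    _, model = family_and_profile
    other = generate_family(FamilySpec(150, 5, 0.08, 0.0, seed=22))
    for m in other.members:
        assert not model.is_member(m)


def test_profile_rejects_empty_sequence(family_and_profile):
    with pytest.raises(ValueError):
        family_and_profile[1].score("")


# ---------------------------------------------------------------------------
# SVM features + training
# ---------------------------------------------------------------------------

def test_feature_vector_contract():
    fam = generate_family(FamilySpec(60, 5, 0.1, 0.0, seed=31))
    from t2pks.alignment import align_score

    scaling = [float(align_score(s, s)) for s in fam.members]
    v = feature_vector(fam.members[0], fam.members, scaling)
    assert v.shape == (5,)
    # self-component dominates raw scores: normalized self equals 1.0
    assert v[0] == pytest.approx(1.0)
    raw = v * np.array(scaling)
    assert np.argmax(raw) == 0
    v2 = feature_vector(fam.members[0], fam.members, scaling)
    assert np.array_equal(v, v2)


@pytest.fixture(scope="module")
def separable_sets():
    fam = generate_family(FamilySpec(100, 10, 0.04, 0.0, seed=41))
    positives = fam.as_dict("pos")
    negs = generate_negatives(10, 100, seed=42, positives=fam.members)
    negatives = {f"neg{i}": s for i, s in enumerate(negs)}
    return positives, negatives


def test_separable_families_reach_perfect_cv_product(separable_sets):
    positives, negatives = separable_sets
    model = train_svm(positives, negatives, seed=7)
    assert model.cv_product == pytest.approx(1.0)
    assert all(model.is_member(s) for s in positives.values())
    assert not any(model.is_member(s) for s in negatives.values())


def test_grid_search_deterministic(separable_sets):
    positives, negatives = separable_sets
    m1 = train_svm(positives, negatives, seed=7)
    m2 = train_svm(positives, negatives, seed=7)
    assert (m1.C, m1.r) == (m2.C, m2.r)


def test_degenerate_single_class_rejected():
    with pytest.raises(ValueError):
        train_svm({"a": "MKT"}, {}, seed=1)


def test_label_permutation_mcc_near_zero(separable_sets):
    positives, negatives = separable_sets
    mccs = label_permutation_mcc(positives, negatives, repeats=10, seed=13)
    assert abs(float(np.mean(mccs))) < 20.0


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

def test_protocol_selection_by_sample_size():
    assert _split_protocol(43) == "4-fold"
    assert _split_protocol(20) == "4-fold"
    assert _split_protocol(5) == "loo"


def test_cv_on_separable_data_is_perfect_and_reproducible(separable_sets):
    positives, negatives = separable_sets
    for kind in ("hmm", "svm"):
        mean, per_repeat = cross_validate(
            kind, positives, negatives, repeats=3, seed=17
        )
        assert mean.AC == pytest.approx(100.0)
        assert all(m.AC == pytest.approx(100.0) for m in per_repeat)
    m1, _ = cross_validate("svm", positives, negatives, repeats=2, seed=17)
    m2, _ = cross_validate("svm", positives, negatives, repeats=2, seed=17)
    assert m1 == m2


# ---------------------------------------------------------------------------
# classify_protein
# ---------------------------------------------------------------------------

def test_reference_member_gets_single_correct_call(refset, bank):
    ks = next(d for d in refset.domains if d.subfamily_key == ("KS", "a"))
    calls = bank.classify_protein(ks.sequence)
    assert len(calls) == 1
    assert calls[0].subfamily_key == ("KS", "a")


def test_didomain_fusion_gets_both_calls(refset, bank):
    kr = next(d for d in refset.domains if d.subfamily_key == ("KR", "a"))
    acp = next(d for d in refset.domains if d.subfamily_key == ("ACP", "a"))
    calls = bank.classify_protein(kr.sequence + acp.sequence)
    assert {c.subfamily_key for c in calls} == {("KR", "a"), ("ACP", "a")}


def test_random_decoys_get_no_calls(bank):
    rng = np.random.default_rng(19)
    for _ in range(100):
        decoy = "".join(rng.choice(list(AA), size=300))
        assert bank.classify_protein(decoy) == []


def test_never_more_than_two_calls(refset, bank):
    ks = next(d for d in refset.domains if d.subfamily_key == ("KS", "a"))
    clf = next(d for d in refset.domains if d.subfamily_key == ("CLF", "a"))
    acp = next(d for d in refset.domains if d.subfamily_key == ("ACP", "a"))
    triple = ks.sequence + clf.sequence + acp.sequence
    assert len(bank.classify_protein(triple)) <= 2


def test_homology_fallback_for_small_subfamilies(refset, bank):
    te = next(d for d in refset.domains if d.subfamily_key == ("TE", "a"))
    calls = bank.classify_protein(te.sequence)
    assert calls and calls[0].method == "homology"
    assert calls[0].subfamily_key == ("TE", "a")
    assert calls[0].evalue <= bank.homology_evalue


def test_bank_round_trips_through_directory(tmp_path, refset, bank):
    bank.save(tmp_path / "bank")
    loaded = ModelBank.load(tmp_path / "bank")
    assert set(loaded.subfamily_keys) == set(bank.subfamily_keys)
    ks = next(d for d in refset.domains if d.subfamily_key == ("KS", "a"))
    orig = bank.classify_protein(ks.sequence)
    back = loaded.classify_protein(ks.sequence)
    assert [(c.subfamily_key, c.method) for c in orig] == [
        (c.subfamily_key, c.method) for c in back
    ]
    # HMMER3 text profiles store probabilities at limited precision
    assert back[0].score == pytest.approx(orig[0].score, rel=1e-4)
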