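"""Per-subfamily type II PKS domain classifiers.

Two classifier types are trained for every subfamily with enough
members (five or more):

* a profile HMM built from a multiple alignment of the member domains
  (HMMER via pyhmmer), with a positive-call bit-score threshold
  calibrated as the minimum training-member self-score minus a margin;
* an RBF-kernel SVM whose feature vector for a query is the vector of
  Smith-Waterman scores against a fixed panel of reference member
  sequences, each normalized by that reference's self-score.  The
  kernel cost C and width r are grid-searched to maximize the
  cross-validated product of sensitivity and specificity.

Evaluation follows the standard protocol for small protein families:
4-fold cross-validation when a subfamily has at least 20 members,
leave-one-out otherwise, averaged over 10 repeats; performance is
reported as sensitivity, specificity, accuracy and Matthews correlation
coefficient, all on a percentage scale.

Subfamilies too small to train on (fewer than five members: KSIII a/b,
AL, MCAT, TE) are handled by best-homolog assignment against their
member sequences, thresholded on an alignment E-value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
import pyhmmer
from sklearn.svm import SVC

from t2pks.alignment import align_score, align_span, evalue_from_score
from t2pks.io_formats import ReferenceDomain

SubfamilyKey = tuple[str, str]

_ALPHABET = pyhmmer.easel.Alphabet.amino()
_BACKGROUND = pyhmmer.plan7.Background(_ALPHABET)

#: Minimum subfamily size for HMM/SVM training; below it, homology fallback.
MIN_TRAINABLE = 5


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True)
class EvaluationMetrics:
    """SN, SP, AC, MCC, all expressed as percentages."""

    SN: float
    SP: float
    AC: float
    MCC: float


def compute_metrics(c: ConfusionCounts) -> EvaluationMetrics:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), AC = (TP+TN)/all, MCC; all x100.

    A zero factor in the MCC denominator yields MCC = 0 by convention.
    Undefined SN/SP (no positives / no negatives) also default to 0.
    """
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all-zero confusion counts")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ac = (tp + tn) / total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom) if denom else 0.0
    return EvaluationMetrics(100 * sn, 100 * sp, 100 * ac, 100 * mcc)


def mean_metrics(metrics: Sequence[EvaluationMetrics]) -> EvaluationMetrics:
    return EvaluationMetrics(
        float(np.mean([m.SN for m in metrics])),
        float(np.mean([m.SP for m in metrics])),
        float(np.mean([m.AC for m in metrics])),
        float(np.mean([m.MCC for m in metrics])),
    )


# ---------------------------------------------------------------------------
# Multiple alignment and profile HMMs
# ---------------------------------------------------------------------------

def build_msa(members: Sequence[str]) -> list[str]:
    """Progressive multiple alignment of member sequences (gapped strings).

    Deterministic for a fixed input order.  A single sequence aligns to
    itself; gap columns use '-'.
    """
    if not members:
        raise ValueError("no sequences to align")
    if len(members) == 1:
        return [members[0]]
    seqs = [bseq.ProteinSequence(s) for s in members]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    aln, _, _, _ = balign.align_multiple(seqs, matrix, gap_penalty=(-11, -1))
    return aln.get_gapped_sequences()


def gappy_columns(msa: Sequence[str], max_gap_frac: float = 0.5) -> list[int]:
    """Indices of alignment columns with a gap fraction above the cutoff."""
    ncol = len(msa[0])
    flagged = []
    for j in range(ncol):
        gaps = sum(row[j] in "-." for row in msa)
        if gaps / len(msa) > max_gap_frac:
            flagged.append(j)
    return flagged


@dataclass
class ProfileModel:
    """Calibrated profile HMM for one subfamily."""

    subfamily_key: SubfamilyKey
    hmm: pyhmmer.plan7.HMM
    threshold: float  # bit score for a positive call
    margin: float = 10.0

    def score(self, seq: str) -> Optional[tuple[float, float, int, int]]:
        """(bit score, E-value, envelope start, envelope end) or None.

        None means the sequence did not survive the HMMER filter
        pipeline at all — far below any calibrated threshold.
        Envelope coordinates are 1-based inclusive on the query.
        """
        if not seq:
            raise ValueError("cannot score an empty sequence")
        dsb = pyhmmer.easel.DigitalSequenceBlock(
            _ALPHABET,
            [pyhmmer.easel.TextSequence(name=b"q", sequence=seq).digitize(_ALPHABET)],
        )
        pipeline = pyhmmer.plan7.Pipeline(_ALPHABET, background=_BACKGROUND, Z=1)
        hits = pipeline.search_hmm(self.hmm, dsb)
        if len(hits) == 0:
            return None
        hit = hits[0]
        dom = hit.best_domain
        return float(hit.score), float(hit.evalue), int(dom.env_from), int(dom.env_to)

    def is_member(self, seq: str) -> bool:
        res = self.score(seq)
        return res is not None and res[0] >= self.threshold


def build_profile(
    msa: Sequence[str],
    subfamily_key: SubfamilyKey = ("NA", "a"),
    members: Optional[Sequence[str]] = None,
    margin: float = 10.0,
    seed: int = 42,
) -> ProfileModel:
    """Build a profile HMM from an MSA and calibrate its call threshold.

    The threshold is a gathering-style cutoff: half the minimum bit
    score of the (unaligned) training members against their own
    profile, and in any case at least ``margin`` bits below that
    minimum.  Setting the cutoff far below the family's own scores is
    what Pfam-style gathering thresholds do — an unseen family member
    scores like another draw from the self-score distribution, while
    true non-members either fail the HMMER filter pipeline outright or
    land orders of magnitude lower in bits; ambiguity between related
    profiles is resolved downstream by competitive call selection, not
    by the per-profile cutoff.
    """
    if not msa:
        raise ValueError("empty alignment")
    name = f"{subfamily_key[0]}_{subfamily_key[1]}".encode()
    tmsa = pyhmmer.easel.TextMSA(
        name=name,
        sequences=[
            pyhmmer.easel.TextSequence(name=f"m{i}".encode(), sequence=row)
            for i, row in enumerate(msa)
        ],
    )
    builder = pyhmmer.plan7.Builder(_ALPHABET, seed=seed)
    hmm, _, _ = builder.build_msa(tmsa.digitize(_ALPHABET), _BACKGROUND)
    model = ProfileModel(subfamily_key, hmm, threshold=-math.inf, margin=margin)
    if members is None:
        members = [row.replace("-", "").replace(".", "") for row in msa]
    self_scores = []
    for m in members:
        res = model.score(m)
        if res is not None:
            self_scores.append(res[0])
    if not self_scores:
        raise ValueError(f"no training member scores against profile {name!r}")
    floor = min(self_scores)
    model.threshold = min(0.5 * floor, floor - margin)
    return model


# ---------------------------------------------------------------------------
# Alignment-score feature SVM
# ---------------------------------------------------------------------------

def feature_vector(
    seq: str,
    reference_seqs: Sequence[str],
    scaling: Sequence[float],
) -> np.ndarray:
    """Normalized Smith-Waterman score of ``seq`` vs each panel sequence.

    Component i is SW(seq, ref_i) / selfscore(ref_i); the scaling
    constants are fixed at training time.
    """
    return np.array(
        [align_score(seq, r) / s for r, s in zip(reference_seqs, scaling)],
        dtype=float,
    )


@dataclass
class SvmModel:
    """RBF-kernel SVM over the alignment-score feature space."""

    subfamily_key: SubfamilyKey
    reference_order: list[str]  # panel member ids
    reference_seqs: list[str]
    scaling: list[float]  # per-panel self-scores
    C: float
    r: float  # RBF width (gamma)
    support_vectors: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    dual_coef: np.ndarray = field(default_factory=lambda: np.empty(0))
    intercept: float = 0.0
    cv_product: float = float("nan")  # CV SN*SP of the winning grid point

    def features(self, seq: str) -> np.ndarray:
        return feature_vector(seq, self.reference_seqs, self.scaling)

    def decision_value(self, x: np.ndarray) -> float:
        d2 = np.sum((self.support_vectors - x) ** 2, axis=1)
        return float(self.dual_coef @ np.exp(-self.r * d2) + self.intercept)

    def is_member(self, seq: str) -> bool:
        return self.decision_value(self.features(seq)) > 0.0


DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_R_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, r: float) -> SVC:
    clf = SVC(C=C, gamma=r, kernel="rbf")
    clf.fit(X, y)
    return clf


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[i::k] for i in range(k)]


def _cv_confusion_svm(
    X: np.ndarray, y: np.ndarray, C: float, r: float, k: int, rng: np.random.Generator
) -> ConfusionCounts:
    """One pass of k-fold (or LOO when k >= n positives) CV confusion."""
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    total = ConfusionCounts(0, 0, 0, 0)
    if k >= len(pos_idx):
        # LOO positives; negatives scored by the all-positive model
        for i in pos_idx:
            train = np.setdiff1d(np.concatenate([pos_idx, neg_idx]), [i])
            clf = _fit_svc(X[train], y[train], C, r)
            pred = clf.predict(X[[i]])[0]
            total += ConfusionCounts(int(pred == 1), 0, 0, int(pred == 0))
        clf = _fit_svc(X, y, C, r)
        pred_neg = clf.predict(X[neg_idx])
        total += ConfusionCounts(
            0, int(np.sum(pred_neg == 0)), int(np.sum(pred_neg == 1)), 0
        )
    else:
        pos_folds = _folds(len(pos_idx), k, rng)
        neg_folds = _folds(len(neg_idx), k, rng)
        for pf, nf in zip(pos_folds, neg_folds):
            test = np.concatenate([pos_idx[pf], neg_idx[nf]])
            train = np.setdiff1d(np.arange(len(y)), test)
            clf = _fit_svc(X[train], y[train], C, r)
            pred = clf.predict(X[test])
            truth = y[test]
            total += ConfusionCounts(
                int(np.sum((pred == 1) & (truth == 1))),
                int(np.sum((pred == 0) & (truth == 0))),
                int(np.sum((pred == 1) & (truth == 0))),
                int(np.sum((pred == 0) & (truth == 1))),
            )
    return total


def train_svm(
    positives: dict[str, str],
    negatives: dict[str, str],
    subfamily_key: SubfamilyKey = ("NA", "a"),
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    seed: int = 42,
    features: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> SvmModel:
    """Grid-search (C, r) by CV product SN x SP, then refit on all data.

    positives/negatives map sequence ids to sequences.  The feature
    panel is the positive set, in its given order.  Ties in the grid
    objective are broken toward smaller C, then smaller r.  The CV
    protocol is 4-fold for >= 20 positives, else leave-one-out.
    """
    if len(positives) < 2:
        raise ValueError("need at least 2 positive sequences")
    if not negatives:
        raise ValueError("need a negative set")
    pos_ids = list(positives)
    pos_seqs = [positives[i] for i in pos_ids]
    neg_seqs = [negatives[i] for i in negatives]
    scaling = [float(align_score(s, s)) for s in pos_seqs]
    if features is None:
        X = np.array(
            [feature_vector(s, pos_seqs, scaling) for s in pos_seqs + neg_seqs]
        )
        y = np.array([1] * len(pos_seqs) + [0] * len(neg_seqs))
    else:
        X, y = features
    k = 4 if len(pos_seqs) >= 20 else len(pos_seqs)
    best = None
    for C in c_grid:
        for r in r_grid:
            rng = np.random.default_rng(seed)
            m = compute_metrics(_cv_confusion_svm(X, y, C, r, k, rng))
            objective = (m.SN / 100) * (m.SP / 100)
            cand = (objective, -C, -r)
            if best is None or cand > best[0]:
                best = (cand, C, r, objective)
    _, C, r, objective = best
    clf = _fit_svc(X, y, C, r)
    return SvmModel(
        subfamily_key=subfamily_key,
        reference_order=pos_ids,
        reference_seqs=pos_seqs,
        scaling=scaling,
        C=C,
        r=r,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        cv_product=objective,
    )


def label_permutation_mcc(
    positives: dict[str, str],
    negatives: dict[str, str],
    repeats: int = 10,
    seed: int = 42,
    C: float = 1.0,
    r: float = 0.125,
) -> list[float]:
    """CV MCC (%) of the SVM under permuted labels, one value per repeat.

    The negative control for the classifier harness: with class labels
    shuffled, cross-validated MCC should sit near zero.
    """
    pos_seqs = [positives[i] for i in positives]
    neg_seqs = [negatives[i] for i in negatives]
    scaling = [float(align_score(s, s)) for s in pos_seqs]
    X = np.array([feature_vector(s, pos_seqs, scaling) for s in pos_seqs + neg_seqs])
    y = np.array([1] * len(pos_seqs) + [0] * len(neg_seqs))
    k = 4 if len(pos_seqs) >= 20 else len(pos_seqs)
    out = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        y_perm = rng.permutation(y)
        counts = _cv_confusion_svm(X, y_perm, C, r, k, rng)
        out.append(compute_metrics(counts).MCC)
    return out


# ---------------------------------------------------------------------------
# Cross-validation harness (both classifier types)
# ---------------------------------------------------------------------------

def _split_protocol(n_pos: int) -> str:
    return "4-fold" if n_pos >= 20 else "loo"


def cross_validate(
    model_spec: str,
    positives: dict[str, str],
    negatives: dict[str, str],
    repeats: int = 10,
    seed: int = 42,
    margin: float = 10.0,
    C: float = 1.0,
    r: float = 0.125,
) -> tuple[EvaluationMetrics, list[EvaluationMetrics]]:
    """Repeated cross-validation of one classifier type.

    model_spec is "hmm" or "svm".  Protocol: 4-fold when there are at
    least 20 positives, leave-one-out otherwise.  In LOO mode each
    positive is held out in turn and the negatives are scored by the
    model trained on all positives (resampled 1:1 per repeat when the
    pool is larger).  Returns (mean metrics, per-repeat metrics).
    """
    pos_ids = list(positives)
    neg_ids = list(negatives)
    protocol = _split_protocol(len(pos_ids))
    per_repeat: list[EvaluationMetrics] = []

    pos_seqs_all = [positives[i] for i in pos_ids]
    if model_spec == "svm":
        scaling = [float(align_score(s, s)) for s in pos_seqs_all]
        feats = {
            i: feature_vector(seq, pos_seqs_all, scaling)
            for i, seq in list(positives.items()) + list(negatives.items())
        }

    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        if protocol == "loo" and len(neg_ids) > len(pos_ids):
            neg_sample = list(rng.choice(neg_ids, size=len(pos_ids), replace=False))
        else:
            neg_sample = neg_ids
        if protocol == "4-fold":
            pos_folds = _folds(len(pos_ids), 4, rng)
            neg_folds = _folds(len(neg_sample), 4, rng)
            fold_pairs = [
                ([pos_ids[i] for i in pf], [neg_sample[i] for i in nf])
                for pf, nf in zip(pos_folds, neg_folds)
            ]
        else:
            fold_pairs = [([p], []) for p in pos_ids]

        total = ConfusionCounts(0, 0, 0, 0)
        for test_pos, test_neg in fold_pairs:
            train_pos = [p for p in pos_ids if p not in test_pos]
            if model_spec == "hmm":
                model = build_profile(
                    build_msa([positives[p] for p in train_pos]),
                    members=[positives[p] for p in train_pos],
                    margin=margin,
                    seed=seed,
                )
                pred_pos = [model.is_member(positives[p]) for p in test_pos]
                pred_neg = [model.is_member(negatives[n]) for n in test_neg]
            else:
                train_neg = [n for n in neg_sample if n not in test_neg]
                Xtr = np.array([feats[i] for i in train_pos + train_neg])
                ytr = np.array([1] * len(train_pos) + [0] * len(train_neg))
                clf = _fit_svc(Xtr, ytr, C, r)
                pred_pos = [
                    clf.predict(feats[p][None, :])[0] == 1 for p in test_pos
                ]
                pred_neg = [
                    clf.predict(feats[n][None, :])[0] == 1 for n in test_neg
                ]
            total += ConfusionCounts(
                sum(pred_pos), sum(not p for p in pred_neg),
                sum(pred_neg), sum(not p for p in pred_pos),
            )
        if protocol == "loo":
            # negatives scored once per repeat by the all-positive model
            if model_spec == "hmm":
                model = build_profile(
                    build_msa(pos_seqs_all),
                    members=pos_seqs_all,
                    margin=margin,
                    seed=seed,
                )
                pred_neg = [model.is_member(negatives[n]) for n in neg_sample]
            else:
                Xtr = np.array([feats[i] for i in pos_ids + neg_sample])
                ytr = np.array([1] * len(pos_ids) + [0] * len(neg_sample))
                clf = _fit_svc(Xtr, ytr, C, r)
                pred_neg = [
                    clf.predict(feats[n][None, :])[0] == 1 for n in neg_sample
                ]
            total += ConfusionCounts(
                0, sum(not p for p in pred_neg), sum(pred_neg), 0
            )
        per_repeat.append(compute_metrics(total))
    return mean_metrics(per_repeat), per_repeat


# ---------------------------------------------------------------------------
# Domain calls and the model bank
# ---------------------------------------------------------------------------

@dataclass
class DomainCall:
    gene_id: str
    subfamily_key: SubfamilyKey
    score: float
    method: str  # HMM | SVM | homology
    evalue: Optional[float] = None
    span: Optional[tuple[int, int]] = None  # 1-based inclusive on the protein


def _span_overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if hi < lo:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / shorter


@dataclass
class ModelBank:
    """Trained per-subfamily models plus the combination policy.

    policy "best_cv" uses, per subfamily, the classifier type with the
    higher cross-validated SN x SP product (ties, and subfamilies
    without CV results, fall to the HMM); "union" calls a domain when
    either model fires; "intersection" requires both.
    """

    profiles: dict[SubfamilyKey, ProfileModel] = field(default_factory=dict)
    svms: dict[SubfamilyKey, SvmModel] = field(default_factory=dict)
    homology_refs: dict[SubfamilyKey, dict[str, str]] = field(default_factory=dict)
    chosen_method: dict[SubfamilyKey, str] = field(default_factory=dict)
    policy: str = "best_cv"
    homology_evalue: float = 1e-10

    @property
    def subfamily_keys(self) -> list[SubfamilyKey]:
        return sorted(set(self.profiles) | set(self.homology_refs))

    # -- training ----------------------------------------------------------

    @classmethod
    def train(
        cls,
        domains: list[ReferenceDomain],
        seed: int = 42,
        with_svm: bool = True,
        margin: float = 10.0,
        policy: str = "best_cv",
    ) -> "ModelBank":
        """Train the full bank from a labeled reference set.

        Negatives for each subfamily's SVM are members of other PKS
        classes plus residue-shuffled positives, sampled 1:1 with the
        positives (seeded).
        """
        rng = np.random.default_rng(seed)
        by_key: dict[SubfamilyKey, list[ReferenceDomain]] = {}
        for d in domains:
            by_key.setdefault(d.subfamily_key, []).append(d)
        bank = cls(policy=policy)
        for key in sorted(by_key):
            members = by_key[key]
            seqs = {d.gene_name: d.sequence for d in members}
            if len(seqs) >= MIN_TRAINABLE:
                msa = build_msa(list(seqs.values()))
                bank.profiles[key] = build_profile(
                    msa, key, members=list(seqs.values()), margin=margin, seed=seed
                )
                if with_svm:
                    negatives = _negative_set(key, seqs, domains, rng)
                    bank.svms[key] = train_svm(
                        seqs, negatives, subfamily_key=key, seed=seed
                    )
                bank.chosen_method[key] = "HMM"
            else:
                bank.homology_refs[key] = seqs
                bank.chosen_method[key] = "homology"
        return bank

    # -- classification ----------------------------------------------------

    def _evaluate_subfamily(self, key: SubfamilyKey, seq: str):
        """Candidate DomainCall for one subfamily, or None."""
        if key in self.homology_refs:
            best = None
            for rid, rseq in self.homology_refs[key].items():
                score, qstart, qend = align_span(seq, rseq)
                ev = evalue_from_score(score, len(seq), len(rseq))
                if ev <= self.homology_evalue and (best is None or score > best[0]):
                    best = (score, ev, qstart, qend)
            if best is None:
                return None
            return DomainCall(
                "", key, best[0], "homology", evalue=best[1], span=(best[2], best[3])
            )

        hmm_res = self.profiles[key].score(seq) if key in self.profiles else None
        hmm_call = None
        if hmm_res is not None and hmm_res[0] >= self.profiles[key].threshold:
            hmm_call = DomainCall(
                "", key, hmm_res[0], "HMM",
                evalue=hmm_res[1], span=(hmm_res[2], hmm_res[3]),
            )
        svm_call = None
        if key in self.svms:
            dv = self.svms[key].decision_value(self.svms[key].features(seq))
            if dv > 0:
                svm_call = DomainCall(
                    "", key, dv, "SVM", evalue=None, span=(1, len(seq))
                )
        if self.policy == "union":
            return hmm_call or svm_call
        if self.policy == "intersection":
            return hmm_call if (hmm_call and svm_call) else None
        # best_cv
        chosen = self.chosen_method.get(key, "HMM")
        return svm_call if chosen == "SVM" else hmm_call

    def classify_protein(
        self,
        seq_or_record,
        max_calls: int = 2,
        max_span_overlap: float = 0.2,
    ) -> list[DomainCall]:
        """Classify one protein; at most ``max_calls`` domain calls.

        Candidate calls are ranked by E-value where available (HMM and
        homology calls), SVM-only calls after them by decision value;
        lower-ranked calls whose spans overlap an accepted call by more
        than ``max_span_overlap`` of the shorter span are dropped.  Per
        PKS class only the best subfamily call survives.
        """
        gene_id = getattr(seq_or_record, "gene_id", "")
        seq = getattr(seq_or_record, "protein_seq", seq_or_record)
        candidates = []
        for key in self.subfamily_keys:
            call = self._evaluate_subfamily(key, seq)
            if call is not None:
                call.gene_id = gene_id
                candidates.append(call)
        candidates.sort(
            key=lambda c: (
                (0, c.evalue, -c.score) if c.evalue is not None else (1, -c.score, 0)
            )
        )
        accepted: list[DomainCall] = []
        for call in candidates:
            if len(accepted) >= max_calls:
                break
            if any(
                call.span and kept.span
                and _span_overlap_frac(call.span, kept.span) > max_span_overlap
                for kept in accepted
            ):
                continue
            accepted.append(call)
        return accepted

    # -- serialization -----------------------------------------------------

    def save(self, out_dir) -> None:
        """Write the bank as a directory of text files.

        One HMMER3 text profile per subfamily, SVM parameters as JSON,
        homology panels as JSON, and a manifest with thresholds and the
        policy.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "policy": self.policy,
            "homology_evalue": self.homology_evalue,
            "subfamilies": {},
        }
        for key, prof in self.profiles.items():
            name = f"{key[0]}_{key[1]}"
            with open(out / f"{name}.hmm", "wb") as fh:
                prof.hmm.write(fh)
            manifest["subfamilies"][name] = {
                "threshold": prof.threshold,
                "margin": prof.margin,
                "chosen_method": self.chosen_method.get(key, "HMM"),
                "has_svm": key in self.svms,
            }
        for key, svm in self.svms.items():
            name = f"{key[0]}_{key[1]}"
            with open(out / f"{name}.svm.json", "w") as fh:
                json.dump(
                    {
                        "reference_order": svm.reference_order,
                        "reference_seqs": svm.reference_seqs,
                        "scaling": svm.scaling,
                        "C": svm.C,
                        "r": svm.r,
                        "support_vectors": svm.support_vectors.tolist(),
                        "dual_coef": svm.dual_coef.tolist(),
                        "intercept": svm.intercept,
                        "cv_product": svm.cv_product,
                    },
                    fh,
                )
        for key, refs in self.homology_refs.items():
            name = f"{key[0]}_{key[1]}"
            with open(out / f"{name}.homology.json", "w") as fh:
                json.dump(refs, fh)
            manifest["subfamilies"][name] = {"chosen_method": "homology"}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, bank_dir) -> "ModelBank":
        bank_dir = Path(bank_dir)
        with open(bank_dir / "manifest.json") as fh:
            manifest = json.load(fh)
        bank = cls(
            policy=manifest["policy"], homology_evalue=manifest["homology_evalue"]
        )
        for name, info in manifest["subfamilies"].items():
            cls_name, sub = name.rsplit("_", 1)
            key = (cls_name, sub)
            if info["chosen_method"] == "homology" and not (bank_dir / f"{name}.hmm").exists():
                with open(bank_dir / f"{name}.homology.json") as fh:
                    bank.homology_refs[key] = json.load(fh)
                bank.chosen_method[key] = "homology"
                continue
            with pyhmmer.plan7.HMMFile(bank_dir / f"{name}.hmm") as hf:
                hmm = hf.read()
            bank.profiles[key] = ProfileModel(
                key, hmm, threshold=info["threshold"], margin=info["margin"]
            )
            bank.chosen_method[key] = info["chosen_method"]
            svm_path = bank_dir / f"{name}.svm.json"
            if svm_path.exists():
                with open(svm_path) as fh:
                    p = json.load(fh)
                bank.svms[key] = SvmModel(
                    subfamily_key=key,
                    reference_order=p["reference_order"],
                    reference_seqs=p["reference_seqs"],
                    scaling=p["scaling"],
                    C=p["C"],
                    r=p["r"],
                    support_vectors=np.array(p["support_vectors"]),
                    dual_coef=np.array(p["dual_coef"]),
                    intercept=p["intercept"],
                    cv_product=p["cv_product"],
                )
        return bank


def _negative_set(
    key: SubfamilyKey,
    positives: dict[str, str],
    all_domains: list[ReferenceDomain],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Negatives: other-class members plus shuffled positives, 1:1 overall."""
    other = [d for d in all_domains if d.pks_class != key[0]]
    n_pos = len(positives)
    n_other = min(len(other), max(1, n_pos // 2))
    chosen = rng.choice(len(other), size=n_other, replace=False) if other else []
    negatives = {f"neg_{other[i].gene_name}": other[i].sequence for i in chosen}
    pos_items = list(positives.items())
    i = 0
    while len(negatives) < n_pos and pos_items:
        pid, seq = pos_items[i % len(pos_items)]
        shuffled = "".join(rng.permutation(list(seq)))
        negatives[f"shuf_{pid}_{i}"] = shuffled
        i += 1
    return negatives


# ---------------------------------------------------------------------------
# Classifier-type comparison harness
# ---------------------------------------------------------------------------

def compare_classifiers(
    domains: list[ReferenceDomain],
    repeats: int = 10,
    seed: int = 42,
    min_members: int = MIN_TRAINABLE,
    subfamily_keys: Optional[Iterable[SubfamilyKey]] = None,
) -> "pd.DataFrame":
    """Per-subfamily CV comparison of the HMM and SVM classifiers.

    Returns a table with both classifiers' SN/SP/AC/MCC and the winner
    per subfamily (higher SN x SP product; ties go to the HMM).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    by_key: dict[SubfamilyKey, list[ReferenceDomain]] = {}
    for d in domains:
        by_key.setdefault(d.subfamily_key, []).append(d)
    keys = sorted(subfamily_keys) if subfamily_keys else sorted(by_key)
    rows = []
    for key in keys:
        members = by_key.get(key, [])
        seqs = {d.gene_name: d.sequence for d in members}
        if len(seqs) < min_members:
            continue
        negatives = _negative_set(key, seqs, domains, rng)
        hmm_m, _ = cross_validate("hmm", seqs, negatives, repeats=repeats, seed=seed)
        svm_grid = train_svm(seqs, negatives, subfamily_key=key, seed=seed)
        svm_m, _ = cross_validate(
            "svm", seqs, negatives, repeats=repeats, seed=seed,
            C=svm_grid.C, r=svm_grid.r,
        )
        hmm_prod = hmm_m.SN * hmm_m.SP
        svm_prod = svm_m.SN * svm_m.SP
        winner = "SVM" if svm_prod > hmm_prod else "HMM"
        rows.append(
            {
                "pks_class": key[0], "subfamily": key[1], "n": len(seqs),
                "hmm_SN": hmm_m.SN, "hmm_SP": hmm_m.SP,
                "hmm_AC": hmm_m.AC, "hmm_MCC": hmm_m.MCC,
                "svm_SN": svm_m.SN, "svm_SP": svm_m.SP,
                "svm_AC": svm_m.AC, "svm_MCC": svm_m.MCC,
                "winner": winner,
            }
        )
    return pd.DataFrame(rows)
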