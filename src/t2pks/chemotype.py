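"""Aromatic polyketide chemotype prediction from ARO/CYC domain combinations.

The ring-folding pattern of a bacterial aromatic polyketide (its
chemotype: angucyclines, anthracyclines, benzoisochromanequinones,
pentangular polyphenols, tetracenomycins, tetracyclines/aureolic acids)
correlates with which aromatase (ARO a-c) and cyclase (CYC a-f)
subfamilies its gene cluster encodes.  The prediction is a two-step
rule engine over a fixed table of 11 known combinations:

1. a cluster whose ARO/CYC subfamily set equals a combination that is
   *unique* to one chemotype is assigned that chemotype directly;
2. a cluster matching a combination shared by two chemotypes is
   resolved by a majority vote over the chemotype labels of its
   ARO/CYC domains' reference homologs;
3. anything else is Unclassified (incomplete domain composition).

By default the signature must equal a rule's combination exactly; a
relaxed mode accepts supersets, preferring the most specific matching
rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import TYPE_CHECKING, Optional

import pandas as pd

from t2pks.alignment import align_score, evalue_from_score
from t2pks.io_formats import ReferenceDomain

if TYPE_CHECKING:  # pragma: no cover
    from t2pks.mining import PksCluster

CHEMOTYPES = (
    "Angucyclines",
    "Anthracyclines",
    "Benzoisochromanequinones",
    "PentangularPolyphenols",
    "Tetracenomycins",
    "Tetracyclines/AureolicAcids",
)

#: Abbreviations used in report tables.
CHEMOTYPE_SHORT = {
    "Angucyclines": "Ang",
    "Anthracyclines": "Ant",
    "Benzoisochromanequinones": "Ben",
    "PentangularPolyphenols": "Pen",
    "Tetracenomycins": "Tcm",
    "Tetracyclines/AureolicAcids": "Tet/Aur",
    "Unclassified": "Unc",
}

UNCLASSIFIED = "Unclassified"

SubfamilyKey = tuple[str, str]


@dataclass(frozen=True)
class ChemotypeRule:
    chemotype: str
    combination: frozenset[SubfamilyKey]
    unique: bool


@dataclass
class RuleTable:
    rules: list[ChemotypeRule]

    def unique_rules(self) -> list[ChemotypeRule]:
        return [r for r in self.rules if r.unique]

    def match_exact(self, signature: frozenset[SubfamilyKey]) -> list[ChemotypeRule]:
        return [r for r in self.rules if r.combination == signature]


@dataclass
class ChemotypePrediction:
    chemotype: str
    rule_path: str  # unique_match | homolog_vote | unclassified
    signature: frozenset = frozenset()
    votes: Optional[dict[str, int]] = None
    ambiguous: bool = False


def _parse_combination(row: pd.Series) -> frozenset[SubfamilyKey]:
    combo = set()
    for col in row.index:
        if "_" in col and int(row[col]) == 1:
            cls, sub = col.split("_")
            combo.add((cls, sub))
    return frozenset(combo)


def load_rule_table() -> RuleTable:
    """Load the embedded combination table and recheck its uniqueness flags."""
    with resources.files("t2pks.data").joinpath("rule_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    rules = []
    combos = [
        (_parse_combination(row), row["chemotype"], bool(row["unique"]))
        for _, row in df.iterrows()
    ]
    for combo, chemo, printed_unique in combos:
        if not combo:
            raise AssertionError("rule table corrupt: empty combination")
        chemos_sharing = {c for cb, c, _ in combos if cb == combo}
        recomputed = len(chemos_sharing) == 1
        if recomputed != printed_unique:
            raise AssertionError(
                f"rule table corrupt: uniqueness flag mismatch for {chemo} {sorted(combo)}"
            )
        rules.append(ChemotypeRule(chemo, combo, recomputed))
    if len(rules) != 11:
        raise AssertionError(f"rule table corrupt: expected 11 rules, got {len(rules)}")
    return RuleTable(rules)


def count_unique(rt: RuleTable) -> int:
    """Number of combinations occurring under exactly one chemotype."""
    return sum(r.unique for r in rt.rules)


def overlapping_pairs(rt: RuleTable) -> set[tuple[str, str]]:
    """Unordered chemotype pairs that share an identical combination."""
    pairs = set()
    for a, b in combinations(rt.rules, 2):
        if a.combination == b.combination and a.chemotype != b.chemotype:
            pairs.add(tuple(sorted((a.chemotype, b.chemotype))))
    return pairs


def signature(cluster: "PksCluster") -> frozenset[SubfamilyKey]:
    """Distinct ARO/CYC subfamily keys among the cluster's domain calls."""
    keys = set()
    for _, calls in cluster.genes:
        for call in calls:
            if call.subfamily_key[0] in ("ARO", "CYC"):
                keys.add(call.subfamily_key)
    return frozenset(keys)


def homolog_vote(
    cluster: "PksCluster",
    reference: list[ReferenceDomain],
    evalue_cutoff: float = 1e-10,
) -> Counter:
    """Chemotype tally over reference homologs of the cluster's ARO/CYC domains.

    Every ARO/CYC domain call contributes all reference ARO/CYC domains
    aligning to its gene's protein with E-value at or under the cutoff
    (not just the best hit); homologs without a chemotype label are
    ignored.
    """
    ref_arocyc = [
        d for d in reference if d.pks_class in ("ARO", "CYC") and d.chemotype
    ]
    tally: Counter = Counter()
    for gene, calls in cluster.genes:
        if not any(c.subfamily_key[0] in ("ARO", "CYC") for c in calls):
            continue
        for ref in ref_arocyc:
            score = align_score(gene.protein_seq, ref.sequence)
            ev = evalue_from_score(score, len(gene.protein_seq), len(ref.sequence))
            if ev <= evalue_cutoff:
                tally[ref.chemotype] += 1
    return tally


def predict_chemotype(
    cluster: "PksCluster",
    rt: RuleTable,
    reference: Optional[list[ReferenceDomain]] = None,
    evalue_cutoff: float = 1e-10,
    relaxed: bool = False,
    votes: Optional[Counter] = None,
) -> ChemotypePrediction:
    """Apply the two-step rule procedure to a validated cluster.

    ``votes`` may be supplied to reuse a precomputed homolog tally;
    otherwise the vote is taken against ``reference`` on demand.
    """
    if not cluster.valid:
        raise ValueError("chemotype prediction requires a valid (KS+CLF) cluster")
    sig = signature(cluster)
    matches = rt.match_exact(sig)
    if not matches and relaxed and sig:
        # most specific rule whose combination the signature contains
        candidates = [r for r in rt.rules if r.combination <= sig]
        if candidates:
            best_size = max(len(r.combination) for r in candidates)
            matches = [r for r in candidates if len(r.combination) == best_size]

    if not matches:
        return ChemotypePrediction(UNCLASSIFIED, "unclassified", sig)

    chemos = sorted({r.chemotype for r in matches})
    if len(chemos) == 1 and all(r.unique for r in matches):
        return ChemotypePrediction(chemos[0], "unique_match", sig)

    if votes is None:
        if reference is None:
            raise ValueError(
                "overlapped combination: reference domains needed for homolog vote"
            )
        votes = homolog_vote(cluster, reference, evalue_cutoff)
    if not votes:
        return ChemotypePrediction(
            UNCLASSIFIED, "unclassified", sig, votes=dict(votes)
        )
    top = max(votes.values())
    winners = sorted(c for c, n in votes.items() if n == top)
    return ChemotypePrediction(
        winners[0],
        "homolog_vote",
        sig,
        votes=dict(votes),
        ambiguous=len(winners) > 1,
    )
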