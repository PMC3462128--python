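"""Cross-genome summaries: per-taxon PKS group ratios and genome tables.

The *taxonomic PKS group ratio* of a taxon (conventionally the
suborder) is the percentage of its sequenced genomes that contain at
least one valid type II PKS gene cluster, reported at two decimals
(half-up rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from t2pks.chemotype import CHEMOTYPE_SHORT, CHEMOTYPES
from t2pks.io_formats import GenomeRecord
from t2pks.mining import MiningResult

#: Published 319-genome actinobacterial survey: per-suborder counts of
#: sequenced genomes and genomes carrying a valid type II PKS cluster,
#: with the reported group ratio (%).  Used as input for ratio checks
#: and as a reference distribution.
ACTINOBACTERIA_SURVEY = (
    ("Acidimicrobiales", "Acidimicrobineae", 1, 0, 0.00),
    ("Actinomycetales", "Actinomycineae", 4, 0, 0.00),
    ("Actinomycetales", "Catenulisporineae", 1, 1, 100.00),
    ("Actinomycetales", "Corynebacterineae", 129, 0, 0.00),
    ("Actinomycetales", "Frankineae", 11, 6, 54.55),
    ("Actinomycetales", "Glycomycineae", 1, 0, 0.00),
    ("Actinomycetales", "Kineosporiineae", 3, 0, 0.00),
    ("Actinomycetales", "Micrococcineae", 48, 1, 2.08),
    ("Actinomycetales", "Micromonosporineae", 7, 5, 71.43),
    ("Actinomycetales", "Propionibacterineae", 12, 0, 0.00),
    ("Actinomycetales", "Pseudonocardineae", 11, 2, 18.18),
    ("Actinomycetales", "Streptomycineae", 36, 6, 16.67),
    ("Actinomycetales", "Streptosporangineae", 7, 4, 57.14),
    ("Bifidobacteriales", "Bifidobacteriaceae", 40, 0, 0.00),
    ("Coriobacteriales", "Coriobacterineae", 6, 0, 0.00),
    ("Rubrobacterales", "Rubrobacterineae", 1, 0, 0.00),
    ("Solirubrobacterales", "Conexibacteraceae", 1, 0, 0.00),
)


@dataclass(frozen=True)
class TaxonSummary:
    order: str
    suborder: str
    n_sequenced: int
    n_with_pks: int
    group_ratio: float  # percent, 2 decimals


def ratio_percent(n_with_pks: int, n_sequenced: int) -> float:
    """100 * n_with_pks / n_sequenced, half-up rounded to 2 decimals."""
    if n_sequenced <= 0:
        raise ValueError("n_sequenced must be positive")
    value = Decimal(100 * n_with_pks) / Decimal(n_sequenced)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def group_ratio(
    genomes: Iterable[tuple[GenomeRecord, MiningResult]],
    rank: str = "suborder",
) -> list[TaxonSummary]:
    """One summary row per taxon at the chosen rank.

    A genome counts as PKS-containing iff its mining result has at
    least one valid cluster.  Genomes without a name at the rank are
    bucketed as "unranked".  Rows sort by (order, suborder).
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for genome, result in genomes:
        order = genome.lineage_at("order") or "unranked"
        taxon = genome.lineage_at(rank) or "unranked"
        bucket = counts.setdefault((order, taxon), [0, 0])
        bucket[0] += 1
        bucket[1] += bool(result.valid_clusters)
    return [
        TaxonSummary(order, taxon, n_seq, n_pks, ratio_percent(n_pks, n_seq))
        for (order, taxon), (n_seq, n_pks) in sorted(counts.items())
    ]


def genome_summary(results: Iterable[MiningResult]) -> pd.DataFrame:
    """One row per PKS-containing genome: size, PKS count, chemotype tally.

    Mirrors the survey-table layout: the chemotype columns (including
    Unc for valid-but-unclassified clusters) count valid clusters per
    predicted chemotype; genomes without a valid cluster are omitted.
    """
    chem_cols = [CHEMOTYPE_SHORT[c] for c in CHEMOTYPES] + ["Unc"]
    rows = []
    for result in results:
        if not result.valid_clusters:
            continue
        tally = dict.fromkeys(chem_cols, 0)
        for cluster in result.valid_clusters:
            if cluster.chemotype is None:
                tally["Unc"] += 1
            else:
                tally[CHEMOTYPE_SHORT[cluster.chemotype.chemotype]] += 1
        rows.append(
            {
                "accession": result.genome_accession,
                "organism": result.organism,
                "size_bp": result.genome_length,
                "n_type2_pks": result.n_pks_proteins_valid,
                **tally,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "organism", "size_bp", "n_type2_pks", *chem_cols],
    )
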