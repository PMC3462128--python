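"""Genome mining: scan proteins, chain hits into clusters, validate.

A genome's proteins are classified one by one against the model bank;
genes carrying at least one type II PKS domain call are then chained
along the chromosome: two hit genes belong to the same candidate
cluster when fewer than ``max_gap`` base pairs (default 15,000,
strictly less) separate their gene bodies, taken transitively.  A
candidate cluster is *valid* — capable in principle of making an
aromatic polyketide — only when it contains both a ketosynthase (KS)
and a chain length factor (CLF) call, the minimal condensing pair.

Strand is ignored for chaining (real type II PKS clusters freely mix
strands) and chaining does not cross the origin of circular genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from t2pks.classifiers import DomainCall, ModelBank
from t2pks.io_formats import GeneRecord, GenomeRecord

DEFAULT_MAX_GAP = 15_000

#: Keywords (lower-case) recognising an existing type II PKS annotation.
KNOWN_PRODUCT_KEYWORDS = (
    "ketosynthase", "keto synthase", "ketoacyl", "beta-ketoacyl",
    "chain length factor", "acyl carrier", "ketoreductase", "keto reductase",
    "aromatase", "cyclase", "acyl-coa ligase", "acyl transferase",
    "acyltransferase", "malonyl", "thioesterase",
)


@dataclass
class PksCluster:
    cluster_id: str
    genome_accession: str
    genes: list[tuple[GeneRecord, list[DomainCall]]]
    valid: bool = False
    chemotype: Optional[object] = None  # ChemotypePrediction, filled downstream
    synthetic_coords: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(g.start for g, _ in self.genes),
            max(g.end for g, _ in self.genes),
        )

    @property
    def pks_classes(self) -> set[str]:
        return {c.subfamily_key[0] for _, calls in self.genes for c in calls}


@dataclass
class MiningResult:
    genome_accession: str
    clusters: list[PksCluster] = field(default_factory=list)
    organism: str = ""
    genome_length: int = 0
    novel_annotations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def valid_clusters(self) -> list[PksCluster]:
        return [c for c in self.clusters if c.valid]

    @property
    def n_pks_proteins(self) -> int:
        """Genes carrying at least one domain call, across all clusters."""
        return sum(
            1 for c in self.clusters for _, calls in c.genes if calls
        )

    @property
    def n_pks_proteins_valid(self) -> int:
        return sum(
            1 for c in self.valid_clusters for _, calls in c.genes if calls
        )


def scan_genome(
    genome: GenomeRecord, bank: ModelBank
) -> list[tuple[GeneRecord, list[DomainCall]]]:
    """Classify every gene; genes without a call are omitted."""
    hits = []
    for gene in genome.genes:
        calls = bank.classify_protein(gene)
        if calls:
            hits.append((gene, calls))
    return hits


def chain_clusters(
    hits: list[tuple[GeneRecord, list[DomainCall]]],
    max_gap: int = DEFAULT_MAX_GAP,
    genome_accession: str = "",
) -> list[PksCluster]:
    """Chain positioned hits into clusters by genomic proximity.

    The gap between two genes is the intervening base pairs between
    their bodies (next.start - prev.end - 1); genes join the same
    cluster iff gap < max_gap, strictly, taken transitively along the
    genome.  Singletons become one-gene clusters.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h[0].start, h[0].end, h[0].gene_id))
    groups: list[list[tuple[GeneRecord, list[DomainCall]]]] = [[ordered[0]]]
    group_end = ordered[0][0].end  # rightmost end of the current group
    for hit in ordered[1:]:
        gap = hit[0].start - group_end - 1
        if gap < max_gap:
            groups[-1].append(hit)
            group_end = max(group_end, hit[0].end)
        else:
            groups.append([hit])
            group_end = hit[0].end
    accession = genome_accession or ordered[0][0].genome_accession
    clusters = [
        PksCluster(
            cluster_id=f"{accession}.cluster{i + 1}",
            genome_accession=accession,
            genes=group,
            synthetic_coords=any(g.synthetic_coords for g, _ in group),
        )
        for i, group in enumerate(groups)
    ]
    return validate_clusters(clusters)


def validate_clusters(clusters: list[PksCluster]) -> list[PksCluster]:
    """valid <=> the cluster has at least one KS call and one CLF call."""
    for cluster in clusters:
        classes = cluster.pks_classes
        cluster.valid = "KS" in classes and "CLF" in classes
    return clusters


def flag_novel_annotations(
    genome: GenomeRecord, clusters: list[PksCluster]
) -> list[tuple[str, str, str]]:
    """Genes called as PKS domains whose prior annotation said otherwise.

    A gene is newly annotated when its product string matches none of
    the known type II PKS class keywords (case-insensitive); a missing
    product counts as "unknown".
    """
    novel = []
    for cluster in clusters:
        for gene, calls in cluster.genes:
            if not calls:
                continue
            product = (gene.product or "unknown").strip()
            if not any(kw in product.lower() for kw in KNOWN_PRODUCT_KEYWORDS):
                key = calls[0].subfamily_key
                novel.append((gene.gene_id, product, f"{key[0]} {key[1]}"))
    return novel


def mine_genome(
    genome: GenomeRecord,
    bank: ModelBank,
    max_gap: int = DEFAULT_MAX_GAP,
    rule_table=None,
    reference=None,
    evalue_cutoff: float = 1e-10,
    relaxed: bool = False,
) -> MiningResult:
    """End-to-end mining of one genome.

    Scans, chains, validates, flags novel annotations and — when a rule
    table is supplied — predicts a chemotype for every valid cluster.
    """
    hits = scan_genome(genome, bank)
    clusters = chain_clusters(hits, max_gap=max_gap, genome_accession=genome.accession)
    result = MiningResult(
        genome_accession=genome.accession,
        clusters=clusters,
        organism=genome.organism,
        genome_length=genome.length_bp,
        novel_annotations=flag_novel_annotations(genome, clusters),
    )
    if rule_table is not None:
        from t2pks.chemotype import predict_chemotype

        for cluster in result.valid_clusters:
            cluster.chemotype = predict_chemotype(
                cluster,
                rule_table,
                reference=reference,
                evalue_cutoff=evalue_cutoff,
                relaxed=relaxed,
            )
    return result
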