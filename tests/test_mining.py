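"""Genome scanning, distance chaining, cluster validation."""

import numpy as np
import pytest

from t2pks.classifiers import DomainCall
from t2pks.io_formats import GeneRecord, GenomeRecord
from t2pks.mining import (
    chain_clusters,
    flag_novel_annotations,
    mine_genome,
    scan_genome,
    validate_clusters,
)


def _hit(gene_id, start, end, cls="KS", sub="a", product=None):
    gene = GeneRecord(
        gene_id, "MKTAYIAK", genome_accession="G1", start=start, end=end,
        product=product,
    )
    return (gene, [DomainCall(gene_id, (cls, sub), 100.0, "HMM")])


def test_gap_strictly_below_15kb_joins():
    hits = [_hit("a", 1, 1000), _hit("b", 16000, 17000, cls="CLF")]
    # gap = 16000 - 1000 - 1 = 14999 < 15000
    clusters = chain_clusters(hits)
    assert len(clusters) == 1 and clusters[0].valid


def test_gap_of_exactly_15kb_splits():
    hits = [_hit("a", 1, 1000), _hit("b", 16001, 17000, cls="CLF")]
    # gap = 16001 - 1000 - 1 = 15000, not < 15000
    clusters = chain_clusters(hits)
    assert len(clusters) == 2
    assert not any(c.valid for c in clusters)


def test_chaining_matches_connected_components_oracle():
    """100 random instances vs brute-force interval-graph components."""
    import networkx as nx

    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(2, 30))
        starts = np.sort(rng.integers(1, 500_000, size=n))
        hits = []
        for i, s in enumerate(starts):
            length = int(rng.integers(300, 3000))
            hits.append(_hit(f"g{i}", int(s), int(s) + length))
        max_gap = int(rng.choice([5_000, 15_000, 40_000]))
        clusters = chain_clusters(hits, max_gap=max_gap)
        got = [{g.gene_id for g, _ in c.genes} for c in clusters]

        g = nx.Graph()
        ordered = sorted(hits, key=lambda h: h[0].start)
        g.add_nodes_from(h[0].gene_id for h in ordered)
        for a, _ in ordered:
            for b, _ in ordered:
                if a is b:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end) - 1
                if gap < max_gap:
                    g.add_edge(a.gene_id, b.gene_id)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(c) for c in got} == oracle


def test_chaining_order_independent_and_monotone():
    rng = np.random.default_rng(3)
    hits = [
        _hit(f"g{i}", int(s), int(s) + 500)
        for i, s in enumerate(sorted(rng.integers(1, 200_000, size=12)))
    ]
    base = chain_clusters(hits)
    shuffled = list(hits)
    rng.shuffle(shuffled)
    again = chain_clusters(shuffled)
    assert [{g.gene_id for g, _ in c.genes} for c in base] == [
        {g.gene_id for g, _ in c.genes} for c in again
    ]
    counts = [len(chain_clusters(hits, max_gap=g)) for g in (1_000, 15_000, 100_000)]
    assert counts == sorted(counts, reverse=True)


def test_empty_inputs():
    assert chain_clusters([]) == []
    genome = GenomeRecord(accession="E", genes=[])
    assert scan_genome(genome, bank=_FakeBank()) == []


class _FakeBank:
    def classify_protein(self, gene):
        return []


@pytest.mark.parametrize(
    "classes,expect_valid",
    [
        (["KS", "CLF", "ACP"], True),
        (["KS"], False),
        (["CLF", "KR"], False),
        (["KS", "CLF"], True),
    ],
)
def test_validity_requires_ks_and_clf(classes, expect_valid):
    hits = [
        _hit(f"g{i}", 1 + i * 2000, 1500 + i * 2000, cls=c)
        for i, c in enumerate(classes)
    ]
    clusters = validate_clusters(chain_clusters(hits))
    assert len(clusters) == 1
    assert clusters[0].valid is expect_valid


def test_scan_finds_exactly_planted_genes(refset, bank, planted_suite):
    _, genome, truth = planted_suite[0]
    hits = scan_genome(genome, bank)
    planted_spans = {(t.span) for t in truth}
    # every hit gene lies inside some planted cluster span; decoys never hit
    for gene, calls in hits:
        assert calls
        assert any(lo <= gene.start <= hi for lo, hi in planted_spans)
    n_planted = sum(len(t.subfamilies) for t in truth)
    assert len(hits) == n_planted


def test_scan_is_order_independent(bank, planted_suite):
    _, genome, _ = planted_suite[0]
    base = {g.gene_id for g, _ in scan_genome(genome, bank)}
    shuffled = GenomeRecord(
        accession=genome.accession,
        genes=list(reversed(genome.genes)),
        length_bp=genome.length_bp,
    )
    assert {g.gene_id for g, _ in scan_genome(shuffled, bank)} == base


def test_novel_annotation_flagging():
    hits = [
        _hit("a", 1, 1000, cls="KS", product="hypothetical protein"),
        _hit("b", 2000, 3000, cls="CLF", product="putative ketosynthase"),
        _hit("c", 4000, 5000, cls="ACP", product=None),
    ]
    clusters = chain_clusters(hits)
    novel = flag_novel_annotations(GenomeRecord(accession="G1"), clusters)
    by_id = {gene_id: (prior, call) for gene_id, prior, call in novel}
    assert "a" in by_id and by_id["a"][0] == "hypothetical protein"
    assert "b" not in by_id  # prior annotation already says ketosynthase
    assert "c" in by_id and by_id["c"][0] == "unknown"


def test_mine_genome_counts(refset, bank, rule_table, planted_suite):
    _, genome, truth = planted_suite[1]
    result = mine_genome(genome, bank, rule_table=rule_table, reference=refset.domains)
    assert result.n_pks_proteins == sum(len(t.subfamilies) for t in truth)
    assert len(result.valid_clusters) == sum(t.valid for t in truth)
    # decoys are hypothetical proteins that received calls? none should
    hit_ids = {g.gene_id for c in result.clusters for g, _ in c.genes}
    assert all("g" in i for i in hit_ids)
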