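"""Synthetic sequence families, reference sets and planted genomes.

Everything in the toolkit is testable offline through this module.  It
emulates the three kinds of data the pipeline consumes:

* divergent protein families with controlled within-family identity
  (descendants of a random ancestor mutated at per-site substitution
  and indel rates);
* negative sequence sets (background-composition random proteins and
  residue-shuffled positives);
* a labeled reference set with the exact subfamily structure of the
  curated type II PKS collection (20 subfamilies over 11 classes,
  308 domains on 280 proteins, including the 28 didomain
  aromatases), each subfamily an independent family;
* genomes with type II PKS gene clusters planted at known coordinates
  among decoy genes, together with a truth table of cluster spans,
  validity and expected chemotype.

Synthetic families descend from random ancestors rather than real PKS
sequences, so the suite carries no download burden; what passing tests
show about real data is discussed in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from t2pks.chemotype import RuleTable, UNCLASSIFIED, load_rule_table
from t2pks.clustering import REFERENCE_SUBFAMILY_STRUCTURE
from t2pks.io_formats import GeneRecord, GenomeRecord, ReferenceDomain

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson-Robinson background amino-acid frequencies.
ROBINSON_FREQS = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}

#: Chemotype labels per ARO/CYC subfamily in the synthetic reference set.
#: Proportions are chosen so that each overlapped rule combination has an
#: unambiguous majority chemotype among its subfamilies' members.
_SYNTHETIC_CHEMOTYPE_LABELS = {
    ("ARO", "a"): (("Anthracyclines", 12), ("Angucyclines", 10),
                   ("Benzoisochromanequinones", 4), ("Tetracyclines/AureolicAcids", 2)),
    ("ARO", "b"): (("Anthracyclines", 12), ("Angucyclines", 10),
                   ("Benzoisochromanequinones", 4), ("Tetracyclines/AureolicAcids", 2)),
    ("ARO", "c"): (("PentangularPolyphenols", 7), ("Tetracenomycins", 4)),
    ("CYC", "a"): (("Angucyclines", 4), ("PentangularPolyphenols", 4),
                   ("Tetracenomycins", 3)),
    ("CYC", "b"): (("PentangularPolyphenols", 6), ("Tetracenomycins", 4)),
    ("CYC", "c"): (("Anthracyclines", 13), ("Tetracyclines/AureolicAcids", 6)),
    ("CYC", "d"): (("Benzoisochromanequinones", 6),),
    ("CYC", "e"): (("Anthracyclines", 3), ("Tetracyclines/AureolicAcids", 2)),
    ("CYC", "f"): (("Anthracyclines", 6),),
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated protein family."""

    ancestor_length: int = 200
    n_members: int = 10
    substitution_rate: float = 0.08
    indel_rate: float = 0.005
    seed: int = 42

    def __post_init__(self):
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass
class Family:
    spec: FamilySpec
    ancestor: str
    members: list[str]

    def as_dict(self, prefix: str = "mem") -> dict[str, str]:
        return {f"{prefix}{i}": s for i, s in enumerate(self.members)}


def _random_protein(rng: np.random.Generator, length: int, composition: str = "uniform") -> str:
    if composition == "robinson":
        letters = list(ROBINSON_FREQS)
        probs = np.array(list(ROBINSON_FREQS.values()))
        probs = probs / probs.sum()
        return "".join(rng.choice(letters, size=length, p=probs))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> str:
    out = []
    for aa in seq:
        u = rng.random()
        if u < indel_rate / 2:
            continue  # deletion
        if u < indel_rate:
            out.append(rng.choice(list(AMINO_ACIDS)))  # insertion before site
        if rng.random() < sub_rate:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out.append(rng.choice(choices))
        else:
            out.append(aa)
    if not out:  # pathological rates on a short ancestor
        out.append(rng.choice(list(AMINO_ACIDS)))
    return "".join(out)


def generate_family(spec: FamilySpec) -> Family:
    """Descendants of a random ancestor, mutated at the spec's rates."""
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_protein(rng, spec.ancestor_length)
    members = [
        _mutate(ancestor, rng, spec.substitution_rate, spec.indel_rate)
        for _ in range(spec.n_members)
    ]
    return Family(spec, ancestor, members)


def generate_negatives(
    n: int,
    lengths: Sequence[int] | int = 300,
    seed: int = 42,
    positives: Optional[Sequence[str]] = None,
    composition: str = "uniform",
) -> list[str]:
    """Background-composition random proteins plus shuffled positives.

    When ``positives`` are supplied, every other output sequence (up to
    availability) is a residue shuffle of a positive — same exact
    composition, no family signal.
    """
    rng = np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = [lengths] * n
    out = []
    pos = list(positives) if positives else []
    for i in range(n):
        if pos and i % 2 == 1:
            src = pos[(i // 2) % len(pos)]
            out.append("".join(rng.permutation(list(src))))
        else:
            out.append(_random_protein(rng, int(lengths[i % len(lengths)]), composition))
    return out


# ---------------------------------------------------------------------------
# Synthetic reference set (the curated-collection emulation)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticReferenceSet:
    domains: list[ReferenceDomain]
    proteins: dict[str, str]  # protein id -> full sequence
    families: dict[tuple[str, str], Family]

    def chemotype_census(self, keys) -> dict[str, int]:
        """Chemotype label counts among members of the given subfamilies."""
        tally: dict[str, int] = {}
        for d in self.domains:
            if d.subfamily_key in set(keys) and d.chemotype:
                tally[d.chemotype] = tally.get(d.chemotype, 0) + 1
        return tally


def make_reference_set(
    seed: int = 42,
    substitution_rate: float = 0.08,
    indel_rate: float = 0.0,
) -> SyntheticReferenceSet:
    """A labeled reference set with the curated subfamily structure.

    Each of the 20 subfamilies is an independent family whose size and
    ancestor length follow the curated table (e.g. KS a: 43 members of
    ~416 aa).  The 28 members of ARO a and ARO b are paired into
    didomain proteins (N-terminal a, C-terminal b), reproducing the
    280-protein / 308-domain bookkeeping.  ARO/CYC members carry
    chemotype labels for homolog voting.
    """
    families: dict[tuple[str, str], Family] = {}
    for i, (cls, sub, n, mean_len) in enumerate(REFERENCE_SUBFAMILY_STRUCTURE):
        families[(cls, sub)] = generate_family(
            FamilySpec(
                ancestor_length=mean_len,
                n_members=n,
                substitution_rate=substitution_rate,
                indel_rate=indel_rate,
                seed=seed * 1000 + i,
            )
        )

    domains: list[ReferenceDomain] = []
    proteins: dict[str, str] = {}

    def labels_for(key, n):
        scheme = _SYNTHETIC_CHEMOTYPE_LABELS.get(key)
        if scheme is None:
            return [None] * n
        out = []
        for chemo, count in scheme:
            out.extend([chemo] * count)
        assert len(out) == n, f"label scheme for {key} covers {len(out)} of {n}"
        return out

    aro_a = families[("ARO", "a")]
    aro_b = families[("ARO", "b")]
    labels_a = labels_for(("ARO", "a"), len(aro_a.members))
    labels_b = labels_for(("ARO", "b"), len(aro_b.members))
    for i, (da, db) in enumerate(zip(aro_a.members, aro_b.members)):
        name = f"aro_ab_{i}"
        proteins[name] = da + db
        domains.append(
            ReferenceDomain(name, da, "ARO", "a", source_cluster=f"cl_ARO_{i}",
                            chemotype=labels_a[i], start=1, end=len(da))
        )
        domains.append(
            ReferenceDomain(name, db, "ARO", "b", source_cluster=f"cl_ARO_{i}",
                            chemotype=labels_b[i], start=len(da) + 1,
                            end=len(da) + len(db))
        )

    for (cls, sub), fam in families.items():
        if (cls, sub) in (("ARO", "a"), ("ARO", "b")):
            continue
        labels = labels_for((cls, sub), len(fam.members))
        for i, seq in enumerate(fam.members):
            name = f"{cls.lower()}_{sub}_{i}"
            proteins[name] = seq
            domains.append(
                ReferenceDomain(name, seq, cls, sub,
                                source_cluster=f"cl_{cls}_{sub}_{i}",
                                chemotype=labels[i])
            )
    return SyntheticReferenceSet(domains, proteins, families)


def write_reference_files(refset: SyntheticReferenceSet, tsv_path, fasta_path) -> None:
    """Write the reference set as the TSV + FASTA pair the loader reads."""
    with open(fasta_path, "w") as fa:
        for name, seq in refset.proteins.items():
            fa.write(f">{name}\n{seq}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("gene_name\tpks_class\tsubfamily\tstart\tend\tsource_cluster\tchemotype\n")
        for d in refset.domains:
            tsv.write(
                f"{d.gene_name}\t{d.pks_class}\t{d.subfamily}\t{d.start}\t{d.end}\t"
                f"{d.source_cluster or '.'}\t{d.chemotype or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Planted genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One planted gene: the subfamily keys its protein carries (1 or 2)."""

    subfamilies: tuple[tuple[str, str], ...]


@dataclass
class ClusterSpec:
    """One planted cluster: genes plus the bp gaps between them."""

    genes: list[GeneSpec]
    gaps: list[int]  # len(genes) - 1 intergenic gaps, bp between gene bodies

    def __post_init__(self):
        if len(self.gaps) != max(0, len(self.genes) - 1):
            raise ValueError("need exactly len(genes) - 1 gaps")


@dataclass
class PlantedGenomeSpec:
    clusters: list[ClusterSpec]
    decoy_genes: int = 10
    inter_cluster_gap: int = 50_000
    decoy_length: int = 300
    #: Per-site substitution rate applied to planted gene proteins.  The
    #: default plants verbatim family members: the HMM call threshold is
    #: calibrated for training-member recall (min self-score - margin), so
    #: only verbatim members carry a detection *guarantee* the truth table
    #: can rely on.  Raise it to probe robustness to divergence.
    mutation_rate: float = 0.0
    seed: int = 42
    accession: str = "SYN0001"
    organism: str = "Syntheticus plantedii"
    lineage: tuple = (("order", "Actinomycetales"), ("suborder", "Synthetineae"))


@dataclass
class ClusterTruth:
    span: tuple[int, int]
    subfamilies: list[tuple[tuple[str, str], ...]]  # per planted gene
    valid: bool
    chemotype: str


def _expected_chemotype(
    signature: frozenset, rt: RuleTable, refset: SyntheticReferenceSet
) -> str:
    """Truth chemotype of a planted signature under the two-rule procedure.

    Unique combination -> its chemotype.  Overlapped combination -> the
    majority chemotype of the reference label census over the
    signature's subfamilies (at fixture divergence levels every
    within-subfamily member is a homolog under the E-value cutoff, so
    the census is the vote).  Anything else -> Unclassified.
    """
    matches = rt.match_exact(signature)
    if not matches:
        return UNCLASSIFIED
    if len(matches) == 1 and matches[0].unique:
        return matches[0].chemotype
    census = refset.chemotype_census(signature)
    if not census:
        return UNCLASSIFIED
    top = max(census.values())
    winners = sorted(c for c, n in census.items() if n == top)
    return winners[0]


def plant_genome(
    spec: PlantedGenomeSpec,
    refset: SyntheticReferenceSet,
    rule_table: Optional[RuleTable] = None,
) -> tuple[GenomeRecord, list[ClusterTruth]]:
    """Build a genome with the specified clusters planted among decoys.

    Each planted gene's protein is a copy of a random member of its
    subfamily's family, mutated at ``spec.mutation_rate`` (didomain
    genes concatenate two such copies).  Decoy genes are
    random-composition proteins placed
    between and around clusters, far enough away never to chain.
    Returns the genome and the per-cluster truth table.
    """
    if rule_table is None:
        rule_table = load_rule_table()
    rng = np.random.default_rng(spec.seed)
    genes: list[GeneRecord] = []
    truths: list[ClusterTruth] = []
    pos = 1
    gene_counter = 0

    def place(protein: str, product: str) -> GeneRecord:
        nonlocal pos, gene_counter
        gene_counter += 1
        span = 3 * (len(protein) + 1)
        rec = GeneRecord(
            gene_id=f"{spec.accession}_g{gene_counter}",
            protein_seq=protein,
            genome_accession=spec.accession,
            start=pos,
            end=pos + span - 1,
            strand="+" if gene_counter % 2 else "-",
            locus_tag=f"SYN_{gene_counter:04d}",
            product=product,
        )
        genes.append(rec)
        return rec

    def planted_protein(subfams: tuple[tuple[str, str], ...]) -> str:
        parts = []
        for key in subfams:
            fam = refset.families[key]
            member = fam.members[int(rng.integers(len(fam.members)))]
            parts.append(_mutate(member, rng, spec.mutation_rate, 0.0))
        return "".join(parts)

    n_lead_decoys = spec.decoy_genes // 2
    for _ in range(n_lead_decoys):
        place(_random_protein(rng, spec.decoy_length), "hypothetical protein")
        pos = genes[-1].end + 1 + spec.inter_cluster_gap

    for cspec in spec.clusters:
        cluster_genes = []
        for i, gspec in enumerate(cspec.genes):
            rec = place(planted_protein(gspec.subfamilies), "hypothetical protein")
            cluster_genes.append(rec)
            if i < len(cspec.gaps):
                pos = rec.end + 1 + cspec.gaps[i]
        pos = cluster_genes[-1].end + 1 + spec.inter_cluster_gap

        # truth: sub-chain the planted genes by the same strict-gap rule
        sub_clusters: list[list[int]] = [[0]]
        for i, gap in enumerate(cspec.gaps):
            if gap < 15_000:
                sub_clusters[-1].append(i + 1)
            else:
                sub_clusters.append([i + 1])
        for idx_group in sub_clusters:
            grp_genes = [cluster_genes[i] for i in idx_group]
            grp_subfams = [cspec.genes[i].subfamilies for i in idx_group]
            flat = {k for subs in grp_subfams for k in subs}
            valid = any(k[0] == "KS" for k in flat) and any(
                k[0] == "CLF" for k in flat
            )
            sig = frozenset(k for k in flat if k[0] in ("ARO", "CYC"))
            chemo = (
                _expected_chemotype(sig, rule_table, refset) if valid else UNCLASSIFIED
            )
            truths.append(
                ClusterTruth(
                    span=(grp_genes[0].start, grp_genes[-1].end),
                    subfamilies=grp_subfams,
                    valid=valid,
                    chemotype=chemo,
                )
            )

    for _ in range(spec.decoy_genes - n_lead_decoys):
        place(_random_protein(rng, spec.decoy_length), "hypothetical protein")
        pos = genes[-1].end + 1 + spec.inter_cluster_gap

    length = genes[-1].end + 1000 if genes else 1000
    starts_ends = sorted((g.start, g.end) for g in genes)
    for (s1, e1), (s2, e2) in zip(starts_ends, starts_ends[1:]):
        if s2 <= e1:
            raise ValueError("overlapping gene placements")
    genome = GenomeRecord(
        accession=spec.accession,
        organism=spec.organism,
        taxon_lineage=list(spec.lineage),
        genes=genes,
        length_bp=length,
    )
    return genome, truths


# Deterministic codon per amino acid for back-translation.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN", "B": "NNN", "Z": "NNN",
}


def write_genbank(genome: GenomeRecord, path, seed: int = 42) -> None:
    """Write a GenomeRecord as a GenBank flat file with CDS features.

    Gene bodies are back-translated with a fixed codon table (plus a
    TAA stop); intergenic space is seeded random DNA, so files are
    byte-reproducible.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rng = np.random.default_rng(seed)
    dna = list(rng.choice(list("ACGT"), size=genome.length_bp))
    features = []
    for gene in genome.genes:
        coding = "".join(_CODON[aa] for aa in gene.protein_seq) + "TAA"
        if gene.strand == "-":
            coding = str(Seq(coding).reverse_complement())
        dna[gene.start - 1 : gene.start - 1 + len(coding)] = list(coding)
        features.append(
            SeqFeature(
                FeatureLocation(gene.start - 1, gene.end, strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "protein_id": [gene.gene_id],
                    "locus_tag": [gene.locus_tag or gene.gene_id],
                    "product": [gene.product or "hypothetical protein"],
                    "translation": [gene.protein_seq],
                },
            )
        )
    record = SeqRecord(
        Seq("".join(dna)),
        id=genome.accession,
        name=genome.accession[:16],
        description=genome.organism,
        features=features,
        annotations={
            "molecule_type": "DNA",
            "organism": genome.organism,
            "taxonomy": [name for _, name in genome.taxon_lineage],
        },
    )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# The standard planted-genome suite (covers every rule row + gap boundary)
# ---------------------------------------------------------------------------

def _minimal_cluster(signature: Sequence[tuple[str, str]], gaps=None) -> ClusterSpec:
    """KS+CLF+ACP backbone plus one gene per ARO/CYC subfamily.

    ARO a and ARO b are planted together as one didomain gene when both
    are requested (as in the curated didomain aromatases).
    """
    keys = list(signature)
    gene_specs = [
        GeneSpec((("KS", "a"),)),
        GeneSpec((("CLF", "a"),)),
        GeneSpec((("ACP", "a"),)),
    ]
    if ("ARO", "a") in keys and ("ARO", "b") in keys:
        gene_specs.append(GeneSpec((("ARO", "a"), ("ARO", "b"))))
        keys = [k for k in keys if k not in (("ARO", "a"), ("ARO", "b"))]
    for k in keys:
        gene_specs.append(GeneSpec((k,)))
    if gaps is None:
        gaps = [2_000] * (len(gene_specs) - 1)
    return ClusterSpec(gene_specs, list(gaps))


def standard_planted_suite(
    refset: SyntheticReferenceSet,
    rule_table: Optional[RuleTable] = None,
    seed: int = 42,
    decoy_genes: int = 6,
) -> list[tuple[PlantedGenomeSpec, GenomeRecord, list[ClusterTruth]]]:
    """Planted genomes covering every rule-table row and the 15 kb boundary.

    One genome per distinct rule combination (8), plus a KS+CLF-only
    genome (Unclassified), a genome whose cluster straddles a 14,999 bp
    gap (joins) and one split by a 15,000 bp gap.
    """
    if rule_table is None:
        rule_table = load_rule_table()
    combos = []
    for rule in rule_table.rules:
        if rule.combination not in combos:
            combos.append(rule.combination)

    suite = []
    genome_idx = 0

    def build(clusters, tag):
        nonlocal genome_idx
        genome_idx += 1
        spec = PlantedGenomeSpec(
            clusters=clusters,
            decoy_genes=decoy_genes,
            seed=seed + genome_idx,
            accession=f"SYN{genome_idx:04d}",
            organism=f"Syntheticus {tag}",
        )
        genome, truth = plant_genome(spec, refset, rule_table)
        suite.append((spec, genome, truth))

    for i, combo in enumerate(combos):
        build([_minimal_cluster(sorted(combo))], f"rule{i + 1}")
    build([_minimal_cluster([])], "unclassified")  # KS+CLF+ACP only
    # cluster straddling a 14,999 bp gap: still one cluster (strict <15k)
    join = _minimal_cluster(sorted(combos[0]))
    join.gaps[-1] = 14_999
    build([join], "joinboundary")
    # 15,000 bp gap between the backbone and the tailoring genes: the
    # chain must split into a valid KS+CLF cluster and an invalid rest.
    split = _minimal_cluster(sorted(combos[0]))
    split.gaps[-1] = 15_000
    build([split], "splitboundary")
    return suite
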