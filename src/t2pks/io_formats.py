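"""Record types and file formats.

The pipeline's currency is the protein-coding gene (:class:`GeneRecord`),
the labeled reference domain (:class:`ReferenceDomain`) and the genome
(:class:`GenomeRecord`).  Coordinates are 1-based inclusive throughout
(GenBank convention); GFF3 output inherits it unchanged.

Readers are thin wrappers over Biopython SeqIO.  Plain protein FASTA has
no genomic coordinates, so :func:`read_protein_fasta` assigns synthetic
ones (consecutive genes, configurable spacing) and flags the record set
accordingly — cluster chaining still works, but reported coordinates are
then bookkeeping, not biology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from t2pks.mining import MiningResult

logger = logging.getLogger(__name__)

#: The eleven type II PKS protein classes.
PKS_CLASSES = (
    "KS", "CLF", "ACP", "KR", "ARO", "CYC", "KSIII", "AL", "AT", "MCAT", "TE",
)

#: The twenty (class, subfamily) pairs of the reference partition.
KNOWN_SUBFAMILIES = (
    ("KS", "a"), ("CLF", "a"), ("ACP", "a"),
    ("KR", "a"), ("KR", "b"),
    ("ARO", "a"), ("ARO", "b"), ("ARO", "c"),
    ("CYC", "a"), ("CYC", "b"), ("CYC", "c"), ("CYC", "d"), ("CYC", "e"), ("CYC", "f"),
    ("KSIII", "a"), ("KSIII", "b"),
    ("AL", "a"), ("AT", "a"), ("MCAT", "a"), ("TE", "a"),
)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GeneRecord:
    """One protein-coding gene with its genomic placement."""

    gene_id: str
    protein_seq: str
    genome_accession: str = ""
    start: int = 1
    end: int = 1
    strand: str = "+"
    locus_tag: Optional[str] = None
    product: Optional[str] = None
    synthetic_coords: bool = False

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise FormatError(f"record {self.gene_id!r}: empty protein sequence")
        bad = set(self.protein_seq.upper()) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.gene_id!r}: non-amino-acid characters {sorted(bad)}"
            )
        self.protein_seq = self.protein_seq.upper()
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"record {self.gene_id!r}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"record {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class ReferenceDomain:
    """A labeled domain of the reference set (one row of the domain table)."""

    gene_name: str
    sequence: str
    pks_class: str
    subfamily: str
    source_cluster: str = ""
    chemotype: Optional[str] = None
    start: int = 1
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end is None:
            self.end = self.start + len(self.sequence) - 1

    @property
    def subfamily_key(self) -> tuple[str, str]:
        return (self.pks_class, self.subfamily)


@dataclass
class GenomeRecord:
    """A genome: metadata plus its protein-coding genes."""

    accession: str
    organism: str = ""
    taxon_lineage: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    length_bp: int = 0

    def lineage_at(self, rank: str) -> Optional[str]:
        for r, name in self.taxon_lineage:
            if r == rank:
                return name
        return None


def read_protein_fasta(
    path, genome_accession: str = "", gene_spacing: int = 1000
) -> list[GeneRecord]:
    """Read a protein FASTA into GeneRecords with synthetic coordinates.

    Genes are laid out in file order: each occupies 3*(len+1) bp and
    consecutive genes are separated by ``gene_spacing`` bp, so distance
    based chaining remains exercisable.  All records are flagged
    ``synthetic_coords=True``.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    pos = 1
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).rstrip("*")
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        span = 3 * (len(seq) + 1)
        records.append(
            GeneRecord(
                gene_id=rec.id,
                protein_seq=seq,
                genome_accession=genome_accession or path.stem,
                start=pos,
                end=pos + span - 1,
                strand="+",
                product=rec.description.partition(" ")[2] or None,
                synthetic_coords=True,
            )
        )
        pos += span + gene_spacing
    if not records:
        logger.warning("FASTA file %s contains no sequences", path)
    return records


def _parse_lineage(annotations: dict) -> list[tuple[str, str]]:
    """Best-effort (rank, name) lineage from GenBank taxonomy annotations.

    GenBank ORGANISM lines carry names only; suborder-level names are
    recognisable by their -ineae suffix (bacterial nomenclature), orders
    by -ales, families by -aceae.  Unrecognised entries keep rank
    'no rank'.
    """
    out = []
    for name in annotations.get("taxonomy", []):
        if name.endswith("ineae"):
            rank = "suborder"
        elif name.endswith("ales"):
            rank = "order"
        elif name.endswith("aceae"):
            rank = "family"
        else:
            rank = "no rank"
        out.append((rank, name))
    return out


def read_genbank(path) -> GenomeRecord:
    """Read a GenBank flat file into a GenomeRecord (one record per file)."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    genes: list[GeneRecord] = []
    for feat in seqrec.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        if "translation" in quals:
            protein = quals["translation"][0]
        else:
            try:
                protein = str(feat.extract(seqrec.seq).translate(to_stop=True))
            except Exception:
                protein = ""
            if not protein:
                logger.warning(
                    "skipping CDS at %s in %s: no translation", feat.location, path
                )
                continue
        gene_id = quals.get("protein_id", quals.get("locus_tag", [None]))[0]
        if gene_id is None:
            gene_id = f"{seqrec.id}_cds{len(genes) + 1}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                protein_seq=protein.rstrip("*"),
                genome_accession=seqrec.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                locus_tag=quals.get("locus_tag", [None])[0],
                product=quals.get("product", [None])[0],
            )
        )
    if not genes:
        raise FormatError(f"GenBank file {path} contains no usable CDS features")
    return GenomeRecord(
        accession=seqrec.id,
        organism=seqrec.annotations.get("organism", ""),
        taxon_lineage=_parse_lineage(seqrec.annotations),
        genes=genes,
        length_bp=len(seqrec.seq),
    )


def load_reference_set(
    tsv_path, fasta_path, permissive: bool = False
) -> list[ReferenceDomain]:
    """Join the reference domain table (TSV) with its protein FASTA.

    The TSV must carry columns gene_name, pks_class, subfamily and may
    carry start, end, source_cluster, chemotype.  When start/end are
    present the domain sequence is the corresponding 1-based inclusive
    slice of the protein; otherwise the whole protein.  A single protein
    may contribute several domain rows (didomain proteins).
    """
    table = pd.read_csv(tsv_path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    required = {"gene_name", "pks_class", "subfamily"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"reference TSV lacks columns: {sorted(missing)}")
    proteins = {rec.id: str(rec.seq).rstrip("*") for rec in SeqIO.parse(str(fasta_path), "fasta")}

    orphans_tsv = sorted(set(table["gene_name"]) - set(proteins))
    orphans_fa = sorted(set(proteins) - set(table["gene_name"]))
    if orphans_tsv or orphans_fa:
        raise FormatError(
            "reference TSV and FASTA ids do not match; "
            f"TSV-only: {orphans_tsv[:5]}, FASTA-only: {orphans_fa[:5]}"
        )

    domains: list[ReferenceDomain] = []
    for row in table.itertuples(index=False):
        key = (row.pks_class, row.subfamily)
        if key not in KNOWN_SUBFAMILIES and not permissive:
            raise FormatError(
                f"unknown (class, subfamily) pair {key} for {row.gene_name}"
            )
        protein = proteins[row.gene_name]
        start = int(getattr(row, "start", "") or 1)
        end_raw = getattr(row, "end", "")
        end = int(end_raw) if end_raw else len(protein)
        if not (1 <= start <= end <= len(protein)):
            raise FormatError(
                f"{row.gene_name}: domain span {start}..{end} outside protein"
            )
        chemotype = getattr(row, "chemotype", "") or None
        domains.append(
            ReferenceDomain(
                gene_name=row.gene_name,
                sequence=protein[start - 1 : end],
                pks_class=row.pks_class,
                subfamily=row.subfamily,
                source_cluster=getattr(row, "source_cluster", "") or "",
                chemotype=chemotype,
                start=start,
                end=end,
            )
        )
    return domains


def class_totals(domains: Iterable[ReferenceDomain]) -> dict[str, int]:
    """Domain count per PKS class (the reference-set bookkeeping)."""
    out: dict[str, int] = {}
    for d in domains:
        out[d.pks_class] = out.get(d.pks_class, 0) + 1
    return out


def n_proteins(domains: Iterable[ReferenceDomain]) -> int:
    return len({d.gene_name for d in domains})


# ---------------------------------------------------------------------------
# Mining reports
# ---------------------------------------------------------------------------

_GFF_HEADER = "##gff-version 3\n"


def _gff_escape(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace("\t", "%09")


def write_mining_report(result: "MiningResult", out_dir) -> dict[str, Path]:
    """Write GFF3 + per-genome and per-protein TSV reports.

    Produces ``clusters.gff3`` (cluster spans and per-domain
    protein_match features), ``genome_summary.tsv`` (one row per genome:
    organism, size, PKS count, chemotype tally) and ``domains.tsv`` (one
    row per domain call).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from t2pks.taxonomy import genome_summary  # local import: avoids a cycle

    gff_path = out_dir / "clusters.gff3"
    with open(gff_path, "w") as fh:
        fh.write(_GFF_HEADER)
        for cluster in result.clusters:
            lo, hi = cluster.span
            attrs = (
                f"ID={_gff_escape(cluster.cluster_id)};valid={str(cluster.valid).lower()}"
            )
            if cluster.chemotype is not None:
                attrs += f";chemotype={_gff_escape(cluster.chemotype.chemotype)}"
            fh.write(
                "\t".join(
                    [
                        result.genome_accession,
                        "t2pks",
                        "gene_cluster",
                        str(lo),
                        str(hi),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for gene, calls in cluster.genes:
                for call in calls:
                    cls, sub = call.subfamily_key
                    fh.write(
                        "\t".join(
                            [
                                result.genome_accession,
                                "t2pks",
                                "protein_match",
                                str(gene.start),
                                str(gene.end),
                                f"{call.score:.1f}",
                                gene.strand,
                                ".",
                                f"ID={_gff_escape(gene.gene_id)};"
                                f"pks_class={cls};subfamily={sub};"
                                f"method={call.method};"
                                f"Parent={_gff_escape(cluster.cluster_id)}",
                            ]
                        )
                        + "\n"
                    )

    summary_path = out_dir / "genome_summary.tsv"
    genome_summary([result]).to_csv(summary_path, sep="\t", index=False)

    rows = []
    for cluster in result.clusters:
        for gene, calls in cluster.genes:
            for call in calls:
                rows.append(
                    {
                        "accession": result.genome_accession,
                        "cluster": cluster.cluster_id,
                        "protein_id": gene.gene_id,
                        "predicted_class": f"{call.subfamily_key[0]} {call.subfamily_key[1]}",
                        "method": call.method,
                        "evalue": call.evalue if call.evalue is not None else ".",
                        "start": gene.start,
                        "end": gene.end,
                        "direction": gene.strand,
                        "locus_tag": gene.locus_tag or ".",
                        "synthetic_coords": gene.synthetic_coords,
                    }
                )
    domains_path = out_dir / "domains.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "accession", "cluster", "protein_id", "predicted_class", "method",
            "evalue", "start", "end", "direction", "locus_tag", "synthetic_coords",
        ],
    ).to_csv(domains_path, sep="\t", index=False)
    return {"gff3": gff_path, "genome_summary": summary_path, "domains": domains_path}
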