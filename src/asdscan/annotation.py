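"""Genome and gene-annotation handling (FASTA + GFF3), 0-based internally.

All internal coordinates are 0-based half-open on the forward strand of the
replicon; sequence extraction reverse-complements for minus-strand features so
that downstream code always sees transcript-orientation sequence.  File I/O
converts to/from each format's native convention (GFF3 is 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "load_genome",
    "load_genes",
    "region_sequence",
    "upstream_sequence",
    "transcribe",
]


@dataclass(frozen=True)
class Gene:
    """A CDS interval: ``start``/``end`` are 0-based half-open genomic."""

    gene_id: str
    replicon: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the A of the (putative) start codon."""
        return self.start if self.strand == "+" else self.end - 1


def load_genome(path: str) -> dict[str, str]:
    """Read a FASTA file into {replicon_id: uppercase DNA string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_genes(path: str, feature_type: str = "CDS") -> list[Gene]:
    """Read CDS features from GFF3 into :class:`Gene` records.

    The gene id is taken from the first available of the ``ID``, ``locus_tag``
    or ``Name`` attributes, falling back to coordinates.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        for key in ("ID", "locus_tag", "Name", "gene"):
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        else:
            gene_id = f"{feat.seqid}:{feat.start}-{feat.end}({feat.strand})"
        genes.append(
            Gene(gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end)
        )
    return genes


def write_gff3(genes: list[Gene], path: str, source: str = "asdscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.replicon}\t{source}\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def region_sequence(
    genome: dict[str, str], replicon: str, strand: str, start: int, end: int
) -> str:
    """Transcript-orientation sequence of a 0-based half-open interval."""
    seq = genome[replicon][start:end]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def upstream_sequence(genome: dict[str, str], gene: Gene, length: int) -> str:
    """The ``length`` nt immediately 5' of the start codon, sense strand.

    Returns a shorter string when the gene sits closer than ``length`` to the
    replicon end (the caller decides whether that is fatal).
    """
    if gene.strand == "+":
        start = max(0, gene.start - length)
        return region_sequence(genome, gene.replicon, "+", start, gene.start)
    end = min(len(genome[gene.replicon]), gene.end + length)
    return region_sequence(genome, gene.replicon, "-", gene.end, end)


def transcribe(dna: str) -> str:
    """DNA -> RNA alphabet (T->U); the sequence is already sense-strand."""
    return dna.replace("T", "U").replace("t", "u")
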