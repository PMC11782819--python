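"""Genome and annotation I/O with strand-aware coordinate handling.

All internal coordinates are 0-based half-open (:class:`Interval`); the GFF3
boundary converts from and to the 1-based inclusive convention used in the
file format. Spacer-internal positions elsewhere in the package use the base
editing convention: the protospacer nucleotide adjacent to the PAM is
position -1 and the PAM-distal end of a 20-nt spacer is position -20.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: Default legal start codons (bacterial; configurable everywhere it matters).
DEFAULT_START_SET = frozenset({"ATG", "GTG"})


class GenomeIOError(ValueError):
    """Raised for malformed FASTA/GFF3 input or coordinate inconsistencies."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the alphabet {A, C, G, T, N}."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, with strand."""

    contig: str
    begin: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise GenomeIOError(
                f"invalid interval [{self.begin}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.begin

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.begin < other.end
            and other.begin < self.end
        )


@dataclass
class Genome:
    """A set of named contigs; the search space for design and scanning."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise GenomeIOError("empty contig id")
            if not seq:
                raise GenomeIOError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeIOError(
                    f"contig {name!r} contains non-IUPAC characters {sorted(bad)}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, interval: Interval) -> str:
        """Strand-aware subsequence: 5'->3' on ``interval.strand``."""
        seq = self.contigs[interval.contig]
        if interval.end > len(seq):
            raise GenomeIOError(
                f"interval {interval} exceeds contig length {len(seq)}"
            )
        sub = seq[interval.begin : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


@dataclass(frozen=True)
class GeneModel:
    """A single-segment CDS: the design target.

    ``start``/``end`` are 1-based inclusive genomic coordinates as in GFF3;
    ``start_codon`` is the first codon read 5'->3' on the coding strand.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    start_codon: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(f"{self.gene_id}: start > end")
        if (self.end - self.start + 1) % 3 != 0:
            raise GenomeIOError(
                f"{self.gene_id}: CDS length {self.end - self.start + 1} "
                "not divisible by 3"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start - 1, self.end, self.strand)

    @property
    def n_codons(self) -> int:
        return (self.end - self.start + 1) // 3

    def codon_interval(self, codon_index: int) -> Interval:
        """Genomic interval of 1-based ``codon_index`` on the coding strand."""
        off = (codon_index - 1) * 3
        if self.strand == "+":
            b = self.start - 1 + off
            return Interval(self.contig, b, b + 3, "+")
        b = self.end - off - 3
        return Interval(self.contig, b, b + 3, "-")

    def codon_base_coord(self, codon_index: int, codon_position: int) -> int:
        """0-based genomic coordinate of one base of a codon (1-based
        ``codon_position`` read 5'->3' on the coding strand)."""
        iv = self.codon_interval(codon_index)
        if self.strand == "+":
            return iv.begin + codon_position - 1
        return iv.end - codon_position


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    Sequences are uppercased on ingest; duplicate ids, empty records and
    non-IUPAC characters are fatal.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeIOError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise GenomeIOError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def extract_cds(genome: Genome, gene: GeneModel) -> str:
    """5'->3' coding sequence; reverse-complemented for minus-strand genes."""
    return genome.fetch(gene.interval)


def _feature_key(attributes) -> str | None:
    for tag in ("ID", "Parent"):
        if tag in attributes:
            return attributes[tag][0]
    return None


def read_gff3(
    path: str | Path,
    genome: Genome,
    start_set: Iterable[str] = DEFAULT_START_SET,
) -> list[GeneModel]:
    """Read single-segment CDS features from a GFF3 file.

    Features typed other than CDS are ignored. A CDS id appearing in more
    than one segment is rejected (bacterial, single-exon scope). A CDS whose
    first codon is not in ``start_set`` is excluded with a warning; CDS
    outside contig bounds or of length not divisible by 3 are fatal.
    """
    start_set = frozenset(s.upper() for s in start_set)
    segments: dict[str, list] = {}
    order: list[str] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "CDS":
            continue
        key = _feature_key(feat.attributes)
        if key is None:
            raise GenomeIOError(
                f"CDS at {feat.seqid}:{feat.start}-{feat.end} lacks ID/Parent"
            )
        if key not in segments:
            order.append(key)
        segments.setdefault(key, []).append(feat)

    genes: list[GeneModel] = []
    for key in order:
        feats = segments[key]
        if len(feats) > 1:
            raise GenomeIOError(
                f"CDS {key!r} has {len(feats)} segments; only single-segment "
                "CDS are supported"
            )
        feat = feats[0]
        if feat.seqid not in genome:
            raise GenomeIOError(f"CDS {key!r} on unknown contig {feat.seqid!r}")
        if feat.start < 1 or feat.end > genome.length(feat.seqid):
            raise GenomeIOError(f"CDS {key!r} outside contig bounds")
        gene = GeneModel(
            gene_id=key,
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            start_codon="NNN",  # placeholder, replaced below
        )
        first = extract_cds(genome, gene)[:3]
        gene = GeneModel(key, feat.seqid, feat.start, feat.end, feat.strand, first)
        if first not in start_set:
            warnings.warn(
                f"CDS {key!r} first codon {first} not in start set "
                f"{sorted(start_set)}; excluded",
                stacklevel=2,
            )
            continue
        genes.append(gene)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\txstart\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )
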