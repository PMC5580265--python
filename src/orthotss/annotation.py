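"""Genome annotations: replicon sequences and ORF records.

Coordinates are 1-based inclusive throughout (GFF3 convention). Strand is
``"+"`` or ``"-"``. An ORF's 5' anchor is ``start`` on the plus strand and
``end`` on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)


@dataclass
class OrfRecord:
    """A protein-coding ORF on one replicon.

    ``start``/``end`` span the full genomic extent including the stop codon.
    ``cds_seq`` is the coding sequence read 5'->3' on the gene strand;
    ``protein_seq`` is its translation without the terminal stop.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    protein_seq: str = ""
    cds_seq: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ORF {self.gene_id}: start > end")
        if self.strand not in STRANDS:
            raise ValueError(f"ORF {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the start codon's first nucleotide."""
        return self.start if self.strand == PLUS else self.end

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a CDS, dropping a terminal stop if present."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class GenomeAnnotation:
    """Replicon sequences plus ORF annotations for one species."""

    species: str
    replicons: dict[str, str]
    orfs: list[OrfRecord] = field(default_factory=list)

    @property
    def replicon_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    def orfs_on(self, replicon: str) -> list[OrfRecord]:
        return sorted(
            (o for o in self.orfs if o.replicon == replicon),
            key=lambda o: (o.start, o.end, o.gene_id),
        )

    def orf_by_id(self, gene_id: str) -> OrfRecord:
        for orf in self.orfs:
            if orf.gene_id == gene_id:
                return orf
        raise KeyError(gene_id)

    def proteome(self) -> dict[str, str]:
        return {o.gene_id: o.protein_seq for o in self.orfs}

    def cds_sequences(self) -> dict[str, str]:
        return {o.gene_id: o.cds_seq for o in self.orfs}

    def sequence(self, replicon: str, start: int, end: int, strand: str = PLUS) -> str:
        """Genomic subsequence on ``strand``, 1-based inclusive coordinates."""
        seq = self.replicons[replicon][start - 1 : end]
        return seq if strand == PLUS else revcomp(seq)

    def upstream_region(self, orf: OrfRecord, length: int) -> tuple[int, int]:
        """Genomic interval (lo, hi) of the ``length`` nt upstream of the
        start codon, truncated at the replicon edge. Empty -> (1, 0)."""
        if orf.strand == PLUS:
            lo = max(1, orf.start - length)
            hi = orf.start - 1
        else:
            lo = orf.end + 1
            hi = min(len(self.replicons[orf.replicon]), orf.end + length)
        return lo, hi

    def upstream_sequence(self, orf: OrfRecord, length: int) -> str:
        """Upstream region read 5'->3' on the gene strand."""
        lo, hi = self.upstream_region(orf, length)
        if lo > hi:
            return ""
        return self.sequence(orf.replicon, lo, hi, orf.strand)
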