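"""Single-copy ortholog detection and alignment coordinate maps.

Candidate cross-species protein hits come from an all-vs-all global
alignment score matrix (a desk-scale stand-in for an all-vs-all BLAST
search; externally computed tabular hits can be ingested instead). A score
floor replaces the e-value cutoff of a real search engine: it is calibrated
so that residue-shuffled protein pairs never reach it. Reciprocal best hits
define candidate orthologs; genes involved in best-hit ties are discarded
(single-copy constraint), and surviving pairs must reach 30% global
identity.

Scoring follows EMBOSS needle defaults: BLOSUM62 with gap open 10 / extend
0.5 for proteins, match 5 / mismatch -4 with the same gap penalties for
nucleotides, and free end gaps.

The protein alignment of each pair is expanded into a codon alignment
(one protein column -> three nucleotide columns) and each gapped alignment
row yields an :class:`AlignmentMap` between ungapped sequence positions and
alignment columns, which downstream code uses to relocate TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import GenomeAnnotation

GAP = "-"


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    _free_end_gaps(aligner)
    return aligner


def make_nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0


def global_align(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment and percent identity.

    Identity = identical columns / alignment length * 100 (gap columns count
    toward the length). Raises on empty input.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_protein_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return row_a, row_b, alignment_identity(row_a, row_b)


def alignment_identity(row_a: str, row_b: str) -> float:
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if not row_a:
        return 0.0
    matches = sum(a == b and a != GAP for a, b in zip(row_a, row_b))
    return 100.0 * matches / len(row_a)


class AlignmentMap:
    """Bijection between ungapped 1-based sequence positions and non-gap
    alignment columns (also 1-based) of one gapped alignment row."""

    def __init__(self, gapped_row: str):
        self.gapped_row = gapped_row
        cols = np.flatnonzero(np.frombuffer(gapped_row.encode(), dtype=np.uint8) != ord(GAP))
        self._col_of_pos = cols + 1
        self._pos_of_col = {int(c) + 1: i + 1 for i, c in enumerate(cols)}

    @property
    def ungapped_length(self) -> int:
        return len(self._col_of_pos)

    def column(self, position: int) -> int:
        if not 1 <= position <= self.ungapped_length:
            raise IndexError(f"position {position} outside sequence")
        return int(self._col_of_pos[position - 1])

    def position(self, column: int) -> int | None:
        """Ungapped position at ``column``; None for a gap column."""
        return self._pos_of_col.get(column)


@dataclass
class OrthologPair:
    """A single-copy orthologous gene pair with its alignments.

    Alignments are stored as gapped row pairs; degapping any row recovers
    the input sequence. ``codon_alignment`` has exactly 3x the protein
    alignment's columns. ``utr_alignment`` pairs the two upstream regions
    (``utr_threshold`` nt each, 5'->3' on the gene strand).
    """

    gene_a: str
    gene_b: str
    protein_identity: float
    protein_alignment: tuple[str, str]
    codon_alignment: tuple[str, str] | None = None
    utr_alignment: tuple[str, str] | None = None


def shuffled_score_threshold(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    n_shuffles: int = 300,
    rng: np.random.Generator | None = None,
    margin: float = 1.0,
) -> float:
    """Score floor for the internal similarity search.

    Scores ``n_shuffles`` random cross-species pairs after residue-shuffling
    one partner and returns the maximum plus ``margin``: no shuffled
    (i.e. compositionally matched but unrelated) pair reaches the floor.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    aligner = make_protein_aligner()
    seqs_a = list(proteome_a.values())
    seqs_b = list(proteome_b.values())
    best = -np.inf
    for _ in range(n_shuffles):
        sa = seqs_a[rng.integers(len(seqs_a))]
        sb = list(seqs_b[rng.integers(len(seqs_b))])
        rng.shuffle(sb)
        best = max(best, aligner.score(sa, "".join(sb)))
    return float(best) + margin


def build_single_copy_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_global_identity: float = 30.0,
    score_threshold: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit single-copy ortholog pairs.

    Hits below ``score_threshold`` (calibrated from shuffled pairs when not
    given) are ignored. Mutual best hits are kept; any gene attaining its
    best score against several partners makes its family ambiguous and all
    its pairs are dropped. Pairs under ``min_global_identity`` percent
    global identity are filtered out. Swapping the two proteomes yields the
    mirrored pair set.
    """
    ids_a, ids_b = list(proteome_a), list(proteome_b)
    shared = set(ids_a) & set(ids_b)
    if shared:
        raise ValueError(f"gene ids not unique across proteomes: {sorted(shared)[:3]}")
    for gid, seq in {**proteome_a, **proteome_b}.items():
        if not seq:
            raise ValueError(f"empty protein sequence for {gid}")
    if score_threshold is None:
        score_threshold = shuffled_score_threshold(proteome_a, proteome_b, rng=rng)
    aligner = make_protein_aligner()
    scores = np.full((len(ids_a), len(ids_b)), -np.inf)
    for i, ga in enumerate(ids_a):
        for j, gb in enumerate(ids_b):
            s = aligner.score(proteome_a[ga], proteome_b[gb])
            if s >= score_threshold:
                scores[i, j] = s

    def best_sets(mat: np.ndarray) -> list[set[int]]:
        out = []
        for row in mat:
            m = row.max()
            out.append(set(np.flatnonzero(row == m)) if np.isfinite(m) else set())
        return out

    best_a = best_sets(scores)          # per a-gene: best b indices
    best_b = best_sets(scores.T)        # per b-gene: best a indices
    mutual = [
        (i, j)
        for i, bs in enumerate(best_a)
        for j in bs
        if i in best_b[j]
    ]
    # single-copy constraint: drop genes appearing in more than one mutual pair
    from collections import Counter

    count_a = Counter(i for i, _ in mutual)
    count_b = Counter(j for _, j in mutual)
    mutual = [(i, j) for i, j in mutual if count_a[i] == 1 and count_b[j] == 1]

    pairs = []
    for i, j in sorted(mutual):
        ga, gb = ids_a[i], ids_b[j]
        row_a, row_b, identity = global_align(proteome_a[ga], proteome_b[gb], aligner)
        if identity >= min_global_identity:
            pairs.append(OrthologPair(ga, gb, identity, (row_a, row_b)))
    return pairs


def degap(row: str) -> str:
    return row.replace(GAP, "")


def build_codon_alignment(pair: OrthologPair, cds_a: str, cds_b: str) -> OrthologPair:
    """Expand the protein alignment into a codon alignment, in place.

    Each protein column becomes 3 nucleotide columns; a gap becomes '---'.
    The CDS must translate column-consistently with the protein (an
    untranslated terminal stop codon is tolerated).
    """
    rows = []
    for prot_row, cds in zip(pair.protein_alignment, (cds_a, cds_b)):
        n_aa = len(degap(prot_row))
        if len(cds) not in (3 * n_aa, 3 * n_aa + 3):
            raise ValueError(
                f"CDS length {len(cds)} inconsistent with {n_aa} aligned residues"
            )
        chunks, k = [], 0
        for ch in prot_row:
            if ch == GAP:
                chunks.append(GAP * 3)
            else:
                chunks.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(chunks))
    pair.codon_alignment = (rows[0], rows[1])
    return pair


def codon_alignment_map(pair: OrthologPair) -> tuple[AlignmentMap, AlignmentMap]:
    """Coordinate maps (ungapped CDS position <-> alignment column) for both
    rows of the codon alignment."""
    if pair.codon_alignment is None:
        raise ValueError("codon alignment not built")
    return AlignmentMap(pair.codon_alignment[0]), AlignmentMap(pair.codon_alignment[1])


def build_utr_alignment(
    pair: OrthologPair,
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    utr_threshold: int = 1000,
    aligner: Align.PairwiseAligner | None = None,
) -> OrthologPair:
    """Align the two upstream (UTR window) regions, in place.

    Regions span ``utr_threshold`` nt upstream of each start codon, read
    5'->3' on the gene strand and truncated at replicon edges.
    """
    if aligner is None:
        aligner = make_nucleotide_aligner()
    utr_a = annotation_a.upstream_sequence(annotation_a.orf_by_id(pair.gene_a), utr_threshold)
    utr_b = annotation_b.upstream_sequence(annotation_b.orf_by_id(pair.gene_b), utr_threshold)
    if not utr_a or not utr_b:
        pair.utr_alignment = None
        return pair
    row_a, row_b, _ = global_align(utr_a, utr_b, aligner)
    pair.utr_alignment = (row_a, row_b)
    return pair


def utr_alignment_map(pair: OrthologPair) -> tuple[AlignmentMap, AlignmentMap]:
    if pair.utr_alignment is None:
        raise ValueError("UTR alignment not built")
    return AlignmentMap(pair.utr_alignment[0]), AlignmentMap(pair.utr_alignment[1])
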