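"""Positional TSS orthology across species and TSS-locus conservation.

For each single-copy ortholog gene pair, TSSs are relocated into a shared
alignment coordinate system: gTSSs into the UTR alignment of the pair,
iTSSs and aTSSs into the codon alignment (an antisense TSS is mapped
through the position of its complementary nucleotide in the sense ORF).
Two TSSs are positional orthologs when their alignment columns are at most
35 apart; column distance counts gap columns, the only definition that does
not depend on which row carries the gaps. Matching is greedy nearest-first
and one-to-one; everything unmatched is a singleton.

A TSS locus is the +/-35 nt window around the TSS; locus identity is the
percent identity of the global nucleotide alignment of the two windows
(strand-aware, truncated at replicon edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import GenomeAnnotation, OrfRecord, PLUS
from .orthology import (
    AlignmentMap,
    OrthologPair,
    codon_alignment_map,
    global_align,
    make_nucleotide_aligner,
    utr_alignment_map,
)
from .tss_inference import TssRecord

ORTHOLOG = "ortholog"
SINGLETON_A = "singleton_a"
SINGLETON_B = "singleton_b"

MATCH_CLASSES = ("g", "a", "i")


@dataclass
class OrthoTssPair:
    """A matched orthologous TSS pair, or an unmatched singleton.

    For singletons the partner fields are None and ``column_distance`` /
    ``locus_identity`` are undefined (None).
    """

    gene_a: str
    gene_b: str
    tss_class: str
    tss_a: TssRecord | None
    tss_b: TssRecord | None
    column_distance: int | None
    pair_status: str
    locus_identity: float | None = None


def utr_index(orf: OrfRecord, utr_length: int, position: int) -> int | None:
    """1-based index of a genomic position within the ORF's UTR window,
    counted 5'->3' on the gene strand; None when outside the window.

    ``utr_length`` is the actual (possibly edge-truncated) window length.
    """
    if utr_length <= 0:
        return None
    if orf.strand == PLUS:
        idx = position - (orf.start - utr_length) + 1
    else:
        idx = (orf.end + utr_length) - position + 1
    return idx if 1 <= idx <= utr_length else None


def cds_index(orf: OrfRecord, position: int) -> int | None:
    """1-based CDS nucleotide index of a genomic position inside the ORF,
    5'->3' on the gene strand; None when outside."""
    if not orf.contains(position):
        return None
    if orf.strand == PLUS:
        return position - orf.start + 1
    return orf.end - position + 1


def map_coordinate_to_column(aln_map: AlignmentMap, region_index: int | None) -> int | None:
    """Alignment column of an ungapped region index; None = NOT_MAPPABLE."""
    if region_index is None or not 1 <= region_index <= aln_map.ungapped_length:
        return None
    return aln_map.column(region_index)


def match_orthologous_tss(
    tss_a: list[tuple[TssRecord, int]],
    tss_b: list[tuple[TssRecord, int]],
    max_col_dist: int = 35,
) -> tuple[list[tuple[TssRecord, TssRecord, int]], list[TssRecord], list[TssRecord]]:
    """Greedy one-to-one matching of (TSS, alignment column) lists.

    Candidate cross pairs are taken in order of ascending column distance
    (ties: smaller column in species A, then in B, then TSS ids); each TSS
    joins at most one pair; pairs beyond ``max_col_dist`` are not formed.
    Returns (pairs, singletons_a, singletons_b). Symmetric in A/B.
    """
    candidates = sorted(
        (
            (abs(ca - cb), ca, cb, ra.tss_id, rb.tss_id, ra, rb)
            for ra, ca in tss_a
            for rb, cb in tss_b
            if abs(ca - cb) <= max_col_dist
        ),
        key=lambda t: t[:5],
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for dist, _, _, ida, idb, ra, rb in candidates:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        pairs.append((ra, rb, dist))
    singles_a = [r for r, _ in tss_a if r.tss_id not in used_a]
    singles_b = [r for r, _ in tss_b if r.tss_id not in used_b]
    return pairs, singles_a, singles_b


def locus_identity(
    annotation_a: GenomeAnnotation,
    tss_a: TssRecord,
    annotation_b: GenomeAnnotation,
    tss_b: TssRecord,
    flank: int = 35,
    aligner=None,
) -> float:
    """Percent identity of the +/-``flank`` nt windows around two TSSs.

    Windows are read 5'->3' on each TSS strand and truncated at replicon
    edges; identity is computed over the global alignment length.
    """
    if aligner is None:
        aligner = make_nucleotide_aligner()
    windows = []
    for ann, tss in ((annotation_a, tss_a), (annotation_b, tss_b)):
        length = len(ann.replicons[tss.replicon])
        lo = max(1, tss.position - flank)
        hi = min(length, tss.position + flank)
        windows.append(ann.sequence(tss.replicon, lo, hi, tss.strand))
    _, _, identity = global_align(windows[0], windows[1], aligner)
    return identity


def _columns_for_class(
    tss_list: list[TssRecord],
    tss_class: str,
    gene_id: str,
    orf: OrfRecord,
    aln_map: AlignmentMap,
    utr_length: int,
) -> list[tuple[TssRecord, int]]:
    out = []
    for tss in tss_list:
        if tss_class not in tss.class_set or tss.associated_orfs.get(tss_class) != gene_id:
            continue
        if tss_class == "g":
            idx = utr_index(orf, utr_length, tss.position)
        else:
            idx = cds_index(orf, tss.position)
        col = map_coordinate_to_column(aln_map, idx)
        if col is not None:
            out.append((tss, col))
    return out


def compare_tss_for_pair(
    pair: OrthologPair,
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    tss_a: list[TssRecord],
    tss_b: list[TssRecord],
    max_col_dist: int = 35,
    flank: int = 35,
    utr_threshold: int = 1000,
    aligner=None,
) -> list[OrthoTssPair]:
    """All per-class match results for one ortholog gene pair.

    A multi-class TSS (e.g. giTSS) participates independently in each of its
    classes. TSSs that cannot be relocated into the pair's alignments are
    left out entirely.
    """
    if aligner is None:
        aligner = make_nucleotide_aligner()
    orf_a = annotation_a.orf_by_id(pair.gene_a)
    orf_b = annotation_b.orf_by_id(pair.gene_b)
    results: list[OrthoTssPair] = []
    for tss_class in MATCH_CLASSES:
        if tss_class == "g":
            if pair.utr_alignment is None:
                continue
            map_a, map_b = utr_alignment_map(pair)
            lo_a, hi_a = annotation_a.upstream_region(orf_a, utr_threshold)
            lo_b, hi_b = annotation_b.upstream_region(orf_b, utr_threshold)
            len_a, len_b = hi_a - lo_a + 1, hi_b - lo_b + 1
        else:
            if pair.codon_alignment is None:
                continue
            map_a, map_b = codon_alignment_map(pair)
            len_a = len_b = 0  # unused for cds mapping
        cols_a = _columns_for_class(tss_a, tss_class, pair.gene_a, orf_a, map_a, len_a)
        cols_b = _columns_for_class(tss_b, tss_class, pair.gene_b, orf_b, map_b, len_b)
        matched, singles_a, singles_b = match_orthologous_tss(cols_a, cols_b, max_col_dist)
        for ra, rb, dist in matched:
            results.append(
                OrthoTssPair(
                    gene_a=pair.gene_a,
                    gene_b=pair.gene_b,
                    tss_class=tss_class,
                    tss_a=ra,
                    tss_b=rb,
                    column_distance=dist,
                    pair_status=ORTHOLOG,
                    locus_identity=locus_identity(
                        annotation_a, ra, annotation_b, rb, flank, aligner
                    ),
                )
            )
        for ra in singles_a:
            results.append(
                OrthoTssPair(pair.gene_a, pair.gene_b, tss_class, ra, None, None, SINGLETON_A)
            )
        for rb in singles_b:
            results.append(
                OrthoTssPair(pair.gene_a, pair.gene_b, tss_class, None, rb, None, SINGLETON_B)
            )
    return results


def compare_all(
    pairs: list[OrthologPair],
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    tss_a: list[TssRecord],
    tss_b: list[TssRecord],
    max_col_dist: int = 35,
    flank: int = 35,
    utr_threshold: int = 1000,
) -> list[OrthoTssPair]:
    aligner = make_nucleotide_aligner()
    results: list[OrthoTssPair] = []
    for pair in pairs:
        results.extend(
            compare_tss_for_pair(
                pair,
                annotation_a,
                annotation_b,
                tss_a,
                tss_b,
                max_col_dist=max_col_dist,
                flank=flank,
                utr_threshold=utr_threshold,
                aligner=aligner,
            )
        )
    return results


def results_to_frame(
    results: list[OrthoTssPair], protein_identities: dict[tuple[str, str], float] | None = None
) -> pd.DataFrame:
    """Tabular view of match results (one row per pair or singleton)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "class": r.tss_class,
                "tss_a": r.tss_a.tss_id if r.tss_a else None,
                "pos_a": r.tss_a.position if r.tss_a else None,
                "strand_a": r.tss_a.strand if r.tss_a else None,
                "tss_b": r.tss_b.tss_id if r.tss_b else None,
                "pos_b": r.tss_b.position if r.tss_b else None,
                "strand_b": r.tss_b.strand if r.tss_b else None,
                "column_distance": r.column_distance,
                "locus_identity": r.locus_identity,
                "pair_status": r.pair_status,
                "protein_identity": (
                    protein_identities.get((r.gene_a, r.gene_b))
                    if protein_identities
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
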