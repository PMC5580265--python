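"""Positional TSS classification relative to ORFs, and -10 box scanning.

Classes: genic (g) when the TSS lies within the UTR window upstream of a
same-strand ORF's start codon; internal (i) when inside a same-strand ORF;
antisense (a) when inside an opposite-strand ORF; intergenic (n) when none
apply. A TSS can carry several classes (giTSS, gaTSS, ...). The genic class
associates with the nearest qualifying downstream ORF only, so each gTSS
defines a single UTR.

"Upstream" is strand-aware: lower coordinates for plus-strand ORFs, higher
coordinates for minus-strand ORFs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .annotation import GenomeAnnotation, OrfRecord, PLUS
from .tss_inference import TssRecord

DEFAULT_UTR_THRESHOLD = 1000


def derive_utr_threshold(annotation: GenomeAnnotation, default: float = DEFAULT_UTR_THRESHOLD) -> float:
    """Mean intergenic distance between consecutive same-replicon ORFs.

    Gap = next.start - prev.end - 1, with negative overlaps counted as 0.
    With no gaps at all (a single ORF), falls back to ``default`` (1000 nt).
    """
    if not annotation.orfs:
        raise ValueError("annotation contains no ORFs")
    gaps: list[float] = []
    for replicon in annotation.replicons:
        orfs = annotation.orfs_on(replicon)
        for prev, nxt in zip(orfs, orfs[1:]):
            gaps.append(max(0, nxt.start - prev.end - 1))
    if not gaps:
        return float(default)
    return float(np.mean(gaps))


def _upstream_distance(tss_pos: int, orf: OrfRecord) -> int:
    """Distance from the TSS to the ORF start codon, along the ORF strand.

    Positive when the TSS is strictly upstream of the start codon.
    """
    if orf.strand == PLUS:
        return orf.start - tss_pos
    return tss_pos - orf.end


def classify_tss(
    tss: TssRecord,
    orfs: list[OrfRecord],
    utr_threshold: float = DEFAULT_UTR_THRESHOLD,
) -> TssRecord:
    """Return a copy of ``tss`` with ``class_set`` and ``associated_orfs`` set.

    Only ORFs on the TSS's replicon are considered. The result does not
    depend on the order of ``orfs``.
    """
    classes: set[str] = set()
    assoc: dict[str, str] = {}
    genic_best: OrfRecord | None = None
    for orf in orfs:
        if orf.replicon != tss.replicon:
            continue
        inside = orf.contains(tss.position)
        if orf.strand == tss.strand:
            if inside:
                classes.add("i")
                assoc["i"] = orf.gene_id
            dist = _upstream_distance(tss.position, orf)
            if 0 < dist <= utr_threshold:
                if genic_best is None or dist < _upstream_distance(tss.position, genic_best):
                    genic_best = orf
        elif inside:
            classes.add("a")
            assoc["a"] = orf.gene_id
    if genic_best is not None:
        classes.add("g")
        assoc["g"] = genic_best.gene_id
    if not classes:
        classes = {"n"}
    return replace(tss, class_set=frozenset(classes), associated_orfs=assoc)


def classify_all(
    tss_list: list[TssRecord],
    annotation: GenomeAnnotation,
    utr_threshold: float = DEFAULT_UTR_THRESHOLD,
) -> list[TssRecord]:
    by_replicon = {rep: annotation.orfs_on(rep) for rep in annotation.replicons}
    return [
        classify_tss(tss, by_replicon.get(tss.replicon, []), utr_threshold)
        for tss in tss_list
    ]


def scan_pribnow(upstream_seq: str, window: tuple[int, int] = (1, 20)) -> list[tuple[int, str]]:
    """Scan for the -10 (Pribnow) box consensus T-A-N-N-N-[T/A].

    ``upstream_seq`` is the region upstream of the TSS, 5'->3' on the TSS
    strand. Offsets are 1-based hexamer start positions within that
    sequence; a hexamer starting at offset o ends len(seq) - o - 4 nt
    upstream of the TSS. Hexamers whose start offset falls inside ``window``
    are reported; a window outside the sequence yields an empty list.
    """
    lo, hi = window
    hits = []
    for offset in range(max(1, lo), min(hi, len(upstream_seq) - 5) + 1):
        hexamer = upstream_seq[offset - 1 : offset + 5]
        if hexamer[0] == "T" and hexamer[1] == "A" and hexamer[5] in "TA":
            hits.append((offset, hexamer))
    return hits
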