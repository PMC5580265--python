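"""Read clipping, alignment filtering, and normalized 5'-end coverage.

dRNA-seq library construction ligates a 3'-poly-A tail before cDNA
synthesis, so reads can carry non-genomic A (3') or T (5') homopolymers.
``clip_read`` removes offending runs, using the longest A/T run observed in
the genome as the threshold for what could still be genomic.

Alignments are kept when they cover at least 80% of the read with at most 4
mismatches and no gaps; reads with several equally best-scoring placements,
or placements inside rRNA operons, are discarded entirely. Per-position
5'-end counts are then normalized by the size of the smallest library so
that libraries are comparable at equal depth.

Alignment records are handled as a :class:`pandas.DataFrame` with the
columns of :data:`ALIGNMENT_COLUMNS`; :class:`ReadAlignmentRecord` is the
single-record view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import MINUS, PLUS, STRANDS

ALIGNMENT_COLUMNS = [
    "read_id",
    "read_length",
    "replicon",
    "start",
    "end",
    "strand",
    "mismatches",
    "gaps",
    "evalue",
    "score",
]


@dataclass
class ReadAlignmentRecord:
    """One alignment of one read; coordinates 1-based inclusive."""

    read_id: str
    read_length: int
    replicon: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    gaps: int = 0
    evalue: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.read_id}: start > end")
        if self.read_length < 1:
            raise ValueError(f"{self.read_id}: read_length < 1")
        if self.mismatches < 0 or self.gaps < 0:
            raise ValueError(f"{self.read_id}: negative mismatches/gaps")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


def records_to_frame(records: list[ReadAlignmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=ALIGNMENT_COLUMNS)


@dataclass
class Library:
    """One sequencing library: its reads plus (condition, TEX state) labels."""

    library_id: str
    condition: str
    tex_state: str
    reads: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ALIGNMENT_COLUMNS))


@dataclass
class CoverageTrack:
    """Strand-specific normalized 5'-end coverage for one library.

    ``data`` maps (replicon, strand) to a float vector whose index 0
    corresponds to genomic position 1.
    """

    library_id: str
    condition: str
    tex_state: str
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def at(self, replicon: str, strand: str, position: int) -> float:
        arr = self.data[(replicon, strand)]
        if not 1 <= position <= len(arr):
            raise IndexError(f"position {position} outside replicon {replicon}")
        return float(arr[position - 1])

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))


def longest_homopolymer(seq: str, base: str) -> int:
    """Length of the longest run of ``base`` in ``seq`` (0 if absent)."""
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def clip_read(seq: str, max_polyA: int, max_polyT: int, min_len: int) -> str | None:
    """Clip ligation-artifact homopolymers; return None (DROP) if too short.

    A trailing A-run strictly longer than ``max_polyA`` (the longest A-run
    observed in the genome) cannot be genomic and is removed in full;
    likewise a leading T-run longer than ``max_polyT``. Reads shorter than
    ``min_len`` after clipping are dropped.
    """
    if not seq:
        return None
    n_a = len(seq) - len(seq.rstrip("A"))
    if n_a > max_polyA:
        seq = seq[: len(seq) - n_a]
    n_t = len(seq) - len(seq.lstrip("T"))
    if n_t > max_polyT:
        seq = seq[n_t:]
    if len(seq) < min_len:
        return None
    return seq


def filter_alignments(
    records: pd.DataFrame,
    rdna_regions: list[tuple[str, int, int]] | None = None,
    min_frac: float = 0.8,
    max_mm: int = 4,
    max_evalue: float = 1e-4,
) -> pd.DataFrame:
    """Apply the mapping filters; keep one unambiguous placement per read.

    A record passes when its alignment spans at least ``min_frac`` of the
    read length, has at most ``max_mm`` mismatches, no gaps, and an e-value
    of at most ``max_evalue``. Among a read's passing records the single
    best-scoring one is kept; a tie among best scores means the read maps
    ambiguously and the read is discarded, as are reads overlapping rRNA
    operon regions. Idempotent and independent of input order.
    """
    if records.empty:
        return records.iloc[0:0].copy()
    df = records
    aln_len = df["end"] - df["start"] + 1
    ok = (
        (aln_len >= min_frac * df["read_length"])
        & (df["mismatches"] <= max_mm)
        & (df["gaps"] == 0)
        & (df["evalue"] <= max_evalue)
    )
    df = df[ok]
    if df.empty:
        return df.copy()
    # unambiguous best placement per read
    best = df.groupby("read_id")["score"].transform("max")
    at_best = df[df["score"] == best]
    n_best = at_best.groupby("read_id")["read_id"].transform("size")
    kept = at_best[n_best == 1]
    if rdna_regions:
        drop = np.zeros(len(kept), dtype=bool)
        for replicon, lo, hi in rdna_regions:
            drop |= (
                (kept["replicon"] == replicon) & (kept["start"] <= hi) & (kept["end"] >= lo)
            ).to_numpy()
        kept = kept[~drop]
    return kept.sort_values(["replicon", "start", "end", "read_id"], kind="stable").reset_index(
        drop=True
    )


def five_prime_positions(frame: pd.DataFrame) -> pd.Series:
    """5' end of each alignment: ``start`` on '+', ``end`` on '-'."""
    return frame["start"].where(frame["strand"] == PLUS, frame["end"])


def coverage_from_alignments(
    libraries: list[Library],
    replicon_lengths: dict[str, int],
    library_sizes: dict[str, int] | None = None,
) -> list[CoverageTrack]:
    """Per-library strand-specific 5'-end coverage, depth-normalized.

    Raw count at position p = number of kept reads whose 5' end maps to p.
    Each library is scaled by min(sizes)/size so every normalized library
    totals the smallest library's raw total. ``library_sizes`` defaults to
    the kept-read counts of the given libraries.
    """
    if library_sizes is None:
        library_sizes = {lib.library_id: len(lib.reads) for lib in libraries}
    for lib_id, size in library_sizes.items():
        if size <= 0:
            raise ValueError(f"library {lib_id} has zero size")
    smallest = min(library_sizes[lib.library_id] for lib in libraries)
    tracks = []
    for lib in libraries:
        scale = smallest / library_sizes[lib.library_id]
        data = {}
        for replicon, length in replicon_lengths.items():
            on_rep = lib.reads[lib.reads["replicon"] == replicon]
            for strand in STRANDS:
                sub = on_rep[on_rep["strand"] == strand]
                pos = five_prime_positions(sub).to_numpy(dtype=np.int64)
                counts = np.bincount(pos - 1, minlength=length).astype(float)
                if len(counts) > length:
                    raise ValueError(f"read beyond end of replicon {replicon}")
                data[(replicon, strand)] = counts * scale
        tracks.append(
            CoverageTrack(
                library_id=lib.library_id,
                condition=lib.condition,
                tex_state=lib.tex_state,
                data=data,
            )
        )
    return tracks
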