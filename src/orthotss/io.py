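"""File formats: FASTA, GFF3, BedGraph, SAM/tabular alignments, TSV tables.

BedGraph files are written per (library, strand) with 0-based half-open
intervals, as the format requires; in-memory coverage stays 1-based.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GenomeAnnotation, MINUS, OrfRecord, PLUS
from .coverage import ALIGNMENT_COLUMNS, CoverageTrack


# --- FASTA ---------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- GFF3 ----------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in annotation.replicons.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for orf in sorted(annotation.orfs, key=lambda o: (o.replicon, o.start)):
            fh.write(
                "\t".join(
                    [
                        orf.replicon,
                        "orthotss",
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        f"ID={orf.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path, replicons: dict[str, str], species: str) -> GenomeAnnotation:
    """Load CDS features into a GenomeAnnotation; sequences are derived
    from the given replicon sequences."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ann = GenomeAnnotation(species, dict(replicons))
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        orf = OrfRecord(
            gene_id=gene_id,
            replicon=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
        )
        cds = ann.sequence(orf.replicon, orf.start, orf.end, orf.strand)
        orf.cds_seq = cds
        from .annotation import translate_cds

        orf.protein_seq = translate_cds(cds)
        ann.orfs.append(orf)
    return ann


# --- BedGraph ------------------------------------------------------------

def _runs(values: np.ndarray):
    """Yield (start_idx, end_idx_exclusive, value) runs of equal value."""
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(values[s])


def write_bedgraph(track: CoverageTrack, out_dir, include_zero: bool = False) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strand, tag in ((PLUS, "fwd"), (MINUS, "rev")):
        path = out_dir / f"{track.library_id}.{tag}.bedgraph"
        with open(path, "w") as fh:
            for (replicon, s), values in sorted(track.data.items()):
                if s != strand:
                    continue
                for lo, hi, value in _runs(values):
                    if value == 0 and not include_zero:
                        continue
                    fh.write(f"{replicon}\t{lo}\t{hi}\t{value:g}\n")
        paths.append(path)
    return paths


def read_bedgraph(
    fwd_path, rev_path, replicon_lengths: dict[str, int],
    library_id: str, condition: str, tex_state: str,
) -> CoverageTrack:
    data = {
        (rep, strand): np.zeros(length)
        for rep, length in replicon_lengths.items()
        for strand in (PLUS, MINUS)
    }
    for path, strand in ((fwd_path, PLUS), (rev_path, MINUS)):
        if not os.path.exists(path):
            continue
        df = pd.read_csv(
            path, sep="\t", header=None, names=["replicon", "start", "end", "value"]
        )
        for row in df.itertuples(index=False):
            data[(row.replicon, strand)][row.start : row.end] = row.value
    return CoverageTrack(library_id, condition, tex_state, data)


# --- alignments ----------------------------------------------------------

def read_alignments_sam(path) -> pd.DataFrame:
    """Mapped reads from a SAM file as an alignment record table.

    Mismatches come from the NM tag minus indel lengths; gaps count
    inserted/deleted bases; the score is the AS tag when present, otherwise
    the aligned length.
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            indels = sum(
                length for op, length in (aln.cigartuples or []) if op in (1, 2)
            )
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            aln_len = aln.reference_end - aln.reference_start
            rows.append(
                {
                    "read_id": aln.query_name,
                    "read_length": aln.query_length or aln.infer_read_length() or aln_len,
                    "replicon": aln.reference_name,
                    "start": aln.reference_start + 1,
                    "end": aln.reference_end,
                    "strand": MINUS if aln.is_reverse else PLUS,
                    "mismatches": int(nm) - indels,
                    "gaps": indels,
                    "evalue": 0.0,
                    "score": float(aln.get_tag("AS")) if aln.has_tag("AS") else float(aln_len),
                }
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_alignments_tabular(path, read_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """12-column tabular (outfmt-6-like) hits as an alignment record table.

    The format carries no read length; it is taken from ``read_lengths``
    when provided, else approximated by the largest query end seen.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=TABULAR_COLUMNS, comment="#")
    strand = np.where(df["sstart"] <= df["send"], PLUS, MINUS)
    start = np.minimum(df["sstart"], df["send"])
    end = np.maximum(df["sstart"], df["send"])
    if read_lengths is not None:
        rlen = df["qseqid"].map(read_lengths)
    else:
        rlen = df.groupby("qseqid")["qend"].transform("max")
    return pd.DataFrame(
        {
            "read_id": df["qseqid"],
            "read_length": rlen.astype(int),
            "replicon": df["sseqid"],
            "start": start.astype(int),
            "end": end.astype(int),
            "strand": strand,
            "mismatches": df["mismatch"].astype(int),
            "gaps": df["gapopen"].astype(int),
            "evalue": df["evalue"].astype(float),
            "score": df["bitscore"].astype(float),
        },
        columns=ALIGNMENT_COLUMNS,
    )


# --- tables --------------------------------------------------------------

def write_tss_table(tss_list, path) -> None:
    """TSSpredator-master-table-like TSV of unified, classified TSSs."""
    rows = []
    for t in tss_list:
        row = {
            "tss_id": t.tss_id,
            "replicon": t.replicon,
            "position": t.position,
            "strand": t.strand,
            "step_height": t.step_height,
            "enrichment": t.enrichment,
            "classes": t.class_label,
        }
        for condition, level in sorted(t.level_by_condition.items()):
            row[f"level_{condition}"] = level
        for cls, gene in sorted(t.associated_orfs.items()):
            row[f"orf_{cls}"] = gene
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ortholog_table(pairs, path) -> None:
    pd.DataFrame(
        [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "protein_identity": p.protein_identity}
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_truth_tables(truth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "species": t.species,
                "truth_id": t.truth_id,
                "replicon": t.replicon,
                "position": t.position,
                "strand": t.strand,
                "class": t.class_label,
                "gene_id": t.gene_id,
                "partner_id": t.partner_id,
                "is_extreme": t.is_extreme,
                **{f"level_{c}": v for c, v in sorted(t.level_by_condition.items())},
            }
            for t in truth.planted_tss
        ]
    ).to_csv(out_dir / "planted_tss.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.ortholog_gene_pairs, columns=["gene_a", "gene_b", "identity_fraction"]
    ).to_csv(out_dir / "ortholog_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.consistent_candidates, columns=["truth_id_a", "truth_id_b"]
    ).to_csv(out_dir / "consistent_candidates.tsv", sep="\t", index=False)
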