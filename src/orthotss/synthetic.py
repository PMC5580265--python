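"""Two-species synthetic world for the comparative dRNA-seq pipeline.

The generator emulates the study design the analysis assumes: two related
genomes that share an ancestral gene order of single-copy orthologous ORFs
and have diverged by nucleotide substitution only (no indels, no
rearrangements); planted TSSs of the four positional classes, a configurable
fraction of which sit at homologous coordinates in both species; and
TEX(+)/TEX(-) 5'-end libraries in two growth conditions (branchless /
true-branching) with Poisson background noise, truncated-Gaussian jitter of
read 5' ends, and TEX(-) signal depleted by the primary-transcript
enrichment factor.

A small subset of orthologous TSS pairs is planted with an extreme,
same-sign condition fold change in both species (the ground truth for the
consistent-candidate screen); all remaining TSSs get mild, independent
condition effects. Everything is driven by one :class:`numpy.random`
generator, so a fixed (config, seed) reproduces the world exactly.

Defaults describe the stated scenario: 200 ortholog pairs, 5% divergence,
and four libraries per species of roughly 1e5 5' ends each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, MINUS, OrfRecord, PLUS, revcomp, translate_cds
from .config import CONDITIONS, ConfigError, TEX_MINUS, TEX_PLUS
from .coverage import ALIGNMENT_COLUMNS, Library

SPECIES = ("species_a", "species_b")
REPLICON = "chr"

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class SimConfig:
    """Parameters of the synthetic world (all randomness flows from ``seed``)."""

    n_ortholog_pairs: int = 200
    n_lineage_specific_tss: int = 100
    divergence: float = 0.05
    fraction_ortho_tss: float = 0.5
    planted_extreme_fraction: float = 0.04
    step_height_range: tuple[float, float] = (80.0, 800.0)
    tex_enrichment: float = 10.0
    background_noise_rate: float = 0.15
    library_sizes: list[int] | None = None
    seed: int = 0
    # genome architecture
    protein_length_range: tuple[int, int] = (100, 250)
    spacer_range: tuple[int, int] = (250, 600)
    utr_offset_range: tuple[int, int] = (20, 150)
    # condition effects (log2 fold changes)
    fc_log2_sd: float = 0.5
    fc_log2_max: float = 1.0
    extreme_log2_fc: float = 4.0
    extreme_level_low: float = 80.0
    # read model
    jitter_sd: float = 1.0
    jitter_max: int = 2
    poisson: bool = True
    read_length: int = 50
    # placement constraints keeping planted truth unambiguous
    min_tss_spacing: int = 60
    cross_offset_spacing: int = 50

    def validate(self) -> "SimConfig":
        for name in ("fraction_ortho_tss", "planted_extreme_fraction", "divergence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_ortholog_pairs < 1:
            raise ConfigError("n_ortholog_pairs must be positive")
        if self.step_height_range[0] <= 0 or self.step_height_range[1] < self.step_height_range[0]:
            raise ConfigError("invalid step_height_range")
        if self.tex_enrichment < 1:
            raise ConfigError("tex_enrichment must be >= 1")
        if self.background_noise_rate < 0 or self.jitter_sd < 0:
            raise ConfigError("rates must be non-negative")
        return self


@dataclass
class PlantedTss:
    species: str
    truth_id: str
    replicon: str
    position: int
    strand: str
    class_label: str
    gene_id: str | None
    partner_id: str | None
    level_by_condition: dict[str, float]
    is_extreme: bool = False


@dataclass
class SyntheticTruth:
    genomes: dict[str, GenomeAnnotation]
    planted_tss: list[PlantedTss]
    ortholog_gene_pairs: list[tuple[str, str, float]]  # (gene_a, gene_b, identity frac)
    consistent_candidates: list[tuple[str, str]]  # (truth_id_a, truth_id_b)

    def planted_for(self, species: str) -> list[PlantedTss]:
        return [t for t in self.planted_tss if t.species == species]

    def by_id(self, truth_id: str) -> PlantedTss:
        for t in self.planted_tss:
            if t.truth_id == truth_id:
                return t
        raise KeyError(truth_id)


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    body = rng.choice(len(_CODONS), size=n_aa - 1)
    return "ATG" + "".join(_CODONS[i] for i in body) + "TAA"


def _mutate_genome(
    rng: np.random.Generator, ancestral: str, orfs: list[OrfRecord], divergence: float
) -> str:
    """Substitute nucleotides at the divergence rate, then revert any
    substitution that created an internal stop codon in an ORF."""
    arr = np.frombuffer(ancestral.encode(), dtype=np.uint8).copy()
    if divergence > 0:
        mask = rng.random(arr.size) < divergence
        code = np.searchsorted(_NT, arr[mask])  # ACGT -> 0..3 (sorted order)
        shift = rng.integers(1, 4, size=mask.sum())
        arr[mask] = _NT[(code + shift) % 4]
    genome = arr.tobytes().decode()
    # repair internal stops codon-by-codon
    chars = list(genome)
    for orf in orfs:
        raw = "".join(chars[orf.start - 1 : orf.end])
        cds = raw if orf.strand == PLUS else revcomp(raw)
        fixed = list(cds)
        for c in range(0, len(cds) - 3, 3):
            if cds[c : c + 3] in _STOPS:
                anc = ancestral[orf.start - 1 : orf.end]
                anc_cds = anc if orf.strand == PLUS else revcomp(anc)
                fixed[c : c + 3] = anc_cds[c : c + 3]
        fixed_cds = "".join(fixed)
        raw_fixed = fixed_cds if orf.strand == PLUS else revcomp(fixed_cds)
        chars[orf.start - 1 : orf.end] = raw_fixed
    return "".join(chars)


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    if sd == 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return float(x)


class _Placer:
    """Bookkeeping that keeps planted TSSs separable by the pipeline."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.positions: dict[tuple[str, str], list[int]] = {}
        self.offsets: dict[tuple[int, str], list[int]] = {}

    def position_free(self, species: str, strand: str, pos: int) -> bool:
        taken = self.positions.get((species, strand), [])
        return all(abs(pos - p) >= self.cfg.min_tss_spacing for p in taken)

    def offset_free(self, gene_idx: int, class_label: str, offset: int) -> bool:
        taken = self.offsets.get((gene_idx, class_label), [])
        return all(abs(offset - o) >= self.cfg.cross_offset_spacing for o in taken)

    def commit(self, species: str, strand: str, pos: int, gene_idx: int | None,
               class_label: str, offset: int | None) -> None:
        self.positions.setdefault((species, strand), []).append(pos)
        if gene_idx is not None and offset is not None:
            self.offsets.setdefault((gene_idx, class_label), []).append(offset)


def _tss_position(orf: OrfRecord, class_label: str, offset: int) -> tuple[int, str]:
    """Genomic (position, strand) of a TSS at a gene-relative offset.

    For 'g' the offset counts nt upstream of the start codon; for 'i'/'a' it
    is the 1-based CDS nucleotide index. Antisense TSSs sit on the strand
    opposite the gene.
    """
    if class_label == "g":
        pos = orf.start - offset if orf.strand == PLUS else orf.end + offset
        return pos, orf.strand
    pos = orf.start + offset - 1 if orf.strand == PLUS else orf.end - offset + 1
    strand = orf.strand if class_label == "i" else (MINUS if orf.strand == PLUS else PLUS)
    return pos, strand


def _sample_offset(rng: np.random.Generator, cfg: SimConfig, orf: OrfRecord,
                   class_label: str) -> int:
    if class_label == "g":
        lo, hi = cfg.utr_offset_range
        return int(rng.integers(lo, hi + 1))
    n_codons = orf.length // 3
    codon = int(rng.integers(3, n_codons - 3))
    return 3 * codon + 1


def _base_levels(rng: np.random.Generator, cfg: SimConfig) -> dict[str, float]:
    lo, hi = cfg.step_height_range
    base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    delta = _truncated_normal(rng, cfg.fc_log2_sd, cfg.fc_log2_max)
    bl, tb = CONDITIONS
    return {bl: base * 2 ** (delta / 2), tb: base * 2 ** (-delta / 2)}


def _extreme_levels(cfg: SimConfig, up_in_branchless: bool) -> dict[str, float]:
    low = cfg.extreme_level_low
    high = low * 2**cfg.extreme_log2_fc
    bl, tb = CONDITIONS
    return {bl: high, tb: low} if up_in_branchless else {bl: low, tb: high}


def generate_truth(cfg: SimConfig) -> SyntheticTruth:
    """Build the two genomes and the planted-TSS ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ortholog_pairs

    # lineage-specific class labels drawn up front so the intergenic desert
    # can be sized for the nTSSs (compact spacers would otherwise put every
    # intergenic position within the 1000 nt genic window of some ORF)
    lineage_classes = {
        sp: [str(c) for c in rng.choice(list("gain"), size=cfg.n_lineage_specific_tss)]
        for sp in SPECIES
    }
    n_desert_slots = sum(cls.count("n") for cls in lineage_classes.values())

    # ancestral genome: spacer, gene, spacer, gene, ..., desert
    lo_aa, hi_aa = cfg.protein_length_range
    parts: list[str] = []
    orfs_proto: list[tuple[int, int, str]] = []  # start, end, strand
    cursor = 0
    for _ in range(n):
        spacer_len = int(rng.integers(*cfg.spacer_range))
        parts.append("".join(chr(b) for b in rng.choice(_NT, size=spacer_len)))
        cursor += spacer_len
        n_aa = int(rng.integers(lo_aa, hi_aa + 1))
        cds = _random_cds(rng, n_aa)
        strand = PLUS if rng.random() < 0.5 else MINUS
        parts.append(cds if strand == PLUS else revcomp(cds))
        orfs_proto.append((cursor + 1, cursor + len(cds), strand))
        cursor += len(cds)
    slot_spacing = 200
    desert_len = 2000 + slot_spacing * max(1, n_desert_slots) + 2000
    parts.append("".join(chr(b) for b in rng.choice(_NT, size=desert_len)))
    ancestral = "".join(parts)
    desert_slots = [cursor + 2000 + slot_spacing * j for j in range(max(1, n_desert_slots))]

    def build_annotation(species: str, genome: str) -> GenomeAnnotation:
        orfs = []
        for k, (start, end, strand) in enumerate(orfs_proto):
            raw = genome[start - 1 : end]
            cds = raw if strand == PLUS else revcomp(raw)
            orfs.append(
                OrfRecord(
                    gene_id=f"{species}_g{k:04d}",
                    replicon=REPLICON,
                    start=start,
                    end=end,
                    strand=strand,
                    cds_seq=cds,
                    protein_seq=translate_cds(cds),
                )
            )
        return GenomeAnnotation(species, {REPLICON: genome}, orfs)

    ann_a = build_annotation(SPECIES[0], ancestral)
    proto_orfs_for_repair = ann_a.orfs  # coordinates shared across species
    genome_b = _mutate_genome(rng, ancestral, proto_orfs_for_repair, cfg.divergence)
    ann_b = build_annotation(SPECIES[1], genome_b)

    pair_identity = []
    for oa, ob in zip(ann_a.orfs, ann_b.orfs):
        same = sum(x == y for x, y in zip(oa.protein_seq, ob.protein_seq))
        pair_identity.append((oa.gene_id, ob.gene_id, same / len(oa.protein_seq)))

    placer = _Placer(cfg)
    planted: list[PlantedTss] = []
    counter = {sp: 0 for sp in SPECIES}
    annotations = {SPECIES[0]: ann_a, SPECIES[1]: ann_b}

    def new_id(species: str) -> str:
        counter[species] += 1
        return f"{species}_t{counter[species]:04d}"

    def try_plant(species: str, gene_idx: int | None, class_label: str,
                  levels: dict[str, float], partner_offset: int | None = None,
                  tries: int = 20) -> PlantedTss | None:
        ann = annotations[species]
        for _ in range(tries):
            if class_label == "n":
                slot = desert_slots[int(rng.integers(len(desert_slots)))]
                pos = slot + int(rng.integers(0, slot_spacing // 2))
                strand = PLUS if rng.random() < 0.5 else MINUS
                offset = None
            else:
                orf = ann.orfs[gene_idx]
                offset = (
                    partner_offset
                    if partner_offset is not None
                    else _sample_offset(rng, cfg, orf, class_label)
                )
                pos, strand = _tss_position(orf, class_label, offset)
            if not placer.position_free(species, strand, pos):
                if partner_offset is not None:
                    return None
                continue
            if offset is not None and partner_offset is None and not placer.offset_free(
                gene_idx, class_label, offset
            ):
                continue
            placer.commit(species, strand, pos, gene_idx, class_label, offset)
            rec = PlantedTss(
                species=species,
                truth_id=new_id(species),
                replicon=REPLICON,
                position=pos,
                strand=strand,
                class_label=class_label,
                gene_id=ann.orfs[gene_idx].gene_id if gene_idx is not None else None,
                partner_id=None,
                level_by_condition=levels,
                is_extreme=False,
            )
            rec._offset = offset  # type: ignore[attr-defined]
            planted.append(rec)
            return rec
        return None

    # one pair event per ortholog gene pair
    ortho_pairs: list[tuple[PlantedTss, PlantedTss]] = []
    for gene_idx in rng.permutation(n):
        gene_idx = int(gene_idx)
        if rng.random() < cfg.fraction_ortho_tss:
            class_label = str(rng.choice(list("gai")))
            orf = ann_a.orfs[gene_idx]
            offset = _sample_offset(rng, cfg, orf, class_label)
            if not placer.offset_free(gene_idx, class_label, offset):
                continue
            base = _base_levels(rng, cfg)
            levels_b = _base_levels(rng, cfg)
            rec_a = try_plant(SPECIES[0], gene_idx, class_label, base, partner_offset=offset)
            if rec_a is None:
                continue
            rec_b = try_plant(SPECIES[1], gene_idx, class_label, levels_b, partner_offset=offset)
            if rec_b is None:
                continue
            rec_a.partner_id = rec_b.truth_id
            rec_b.partner_id = rec_a.truth_id
            ortho_pairs.append((rec_a, rec_b))
        else:
            for species in SPECIES:
                class_label = str(rng.choice(list("gai")))
                try_plant(species, gene_idx, class_label, _base_levels(rng, cfg))

    # extra lineage-specific TSSs
    for species in SPECIES:
        for class_label in lineage_classes[species]:
            gene_idx = None if class_label == "n" else int(rng.integers(n))
            try_plant(species, gene_idx, class_label, _base_levels(rng, cfg))

    # plant consistent extreme fold changes on a subset of orthologous pairs
    n_extreme = int(round(cfg.planted_extreme_fraction * len(ortho_pairs)))
    consistent: list[tuple[str, str]] = []
    if n_extreme > 0 and ortho_pairs:
        chosen = rng.choice(len(ortho_pairs), size=min(n_extreme, len(ortho_pairs)), replace=False)
        for idx in sorted(int(i) for i in chosen):
            rec_a, rec_b = ortho_pairs[idx]
            up = bool(rng.random() < 0.5)
            for rec in (rec_a, rec_b):
                rec.level_by_condition = _extreme_levels(cfg, up)
                rec.is_extreme = True
            consistent.append((rec_a.truth_id, rec_b.truth_id))

    return SyntheticTruth(
        genomes=annotations,
        planted_tss=planted,
        ortholog_gene_pairs=pair_identity,
        consistent_candidates=consistent,
    )


def _jitter_weights(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.arange(-cfg.jitter_max, cfg.jitter_max + 1)
    if cfg.jitter_sd == 0:
        w = (offsets == 0).astype(float)
    else:
        w = np.exp(-(offsets.astype(float) ** 2) / (2 * cfg.jitter_sd**2))
    return offsets, w / w.sum()


def expected_intensity(
    truth: SyntheticTruth, cfg: SimConfig, species: str, condition: str, tex_state: str
) -> dict[tuple[str, str], np.ndarray]:
    """Expected per-position 5'-end rate for one library (before sampling)."""
    genome = truth.genomes[species]
    length = len(genome.replicons[REPLICON])
    offsets, weights = _jitter_weights(cfg)
    lam = {(REPLICON, s): np.full(length, float(cfg.background_noise_rate)) for s in (PLUS, MINUS)}
    depletion = 0.0 if math.isinf(cfg.tex_enrichment) else 1.0 / cfg.tex_enrichment
    factor = 1.0 if tex_state == TEX_PLUS else depletion
    for tss in truth.planted_for(species):
        level = tss.level_by_condition[condition] * factor
        if level <= 0:
            continue
        arr = lam[(tss.replicon, tss.strand)]
        for off, w in zip(offsets, weights):
            p = tss.position + int(off)
            if 1 <= p <= length:
                arr[p - 1] += level * w
    return lam


@dataclass
class SimulationOutput:
    truth: SyntheticTruth
    libraries: dict[str, list[Library]] = field(default_factory=dict)

    def library(self, species: str, condition: str, tex_state: str) -> Library:
        for lib in self.libraries[species]:
            if lib.condition == condition and lib.tex_state == tex_state:
                return lib
        raise KeyError((species, condition, tex_state))


def _reads_from_counts(
    counts: dict[tuple[str, str], np.ndarray], cfg: SimConfig, library_id: str
) -> pd.DataFrame:
    frames = []
    next_id = 0
    for (replicon, strand), arr in sorted(counts.items()):
        pos = np.flatnonzero(arr > 0) + 1
        reps = arr[pos - 1].astype(int)
        p5 = np.repeat(pos, reps)
        if strand == PLUS:
            start = p5
            end = np.minimum(p5 + cfg.read_length - 1, len(arr))
        else:
            end = p5
            start = np.maximum(p5 - cfg.read_length + 1, 1)
        m = len(p5)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": np.arange(next_id, next_id + m),
                    "read_length": end - start + 1,
                    "replicon": replicon,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "mismatches": 0,
                    "gaps": 0,
                    "evalue": 1e-30,
                    "score": (end - start + 1).astype(float),
                }
            )
        )
        next_id += m
    if not frames:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_libraries(truth: SyntheticTruth, cfg: SimConfig) -> SimulationOutput:
    """Emit per-library alignment records for both species.

    With ``cfg.poisson`` and no fixed library sizes, per-position counts are
    Poisson around the expected intensity. With ``library_sizes`` set, each
    library draws exactly that many 5' ends (multinomial over the intensity
    profile). With ``poisson=False`` and no sizes, counts are the rounded
    intensities (the deterministic, zero-sampling-noise limit).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    out = SimulationOutput(truth=truth)
    lib_specs = [
        (condition, tex) for condition in CONDITIONS for tex in (TEX_PLUS, TEX_MINUS)
    ]
    for species in SPECIES:
        libs = []
        for k, (condition, tex) in enumerate(lib_specs):
            lam = expected_intensity(truth, cfg, species, condition, tex)
            counts: dict[tuple[str, str], np.ndarray] = {}
            if cfg.library_sizes is not None:
                size = int(cfg.library_sizes[k])
                keys = sorted(lam)
                flat = np.concatenate([lam[k2] for k2 in keys])
                total = flat.sum()
                if total <= 0:
                    raise ConfigError("cannot draw reads from an all-zero profile")
                drawn = rng.multinomial(size, flat / total)
                splits = np.cumsum([len(lam[k2]) for k2 in keys])[:-1]
                for k2, chunk in zip(keys, np.split(drawn, splits)):
                    counts[k2] = chunk.astype(float)
            elif cfg.poisson:
                counts = {k2: rng.poisson(a).astype(float) for k2, a in lam.items()}
            else:
                counts = {k2: np.rint(a) for k2, a in lam.items()}
            library_id = f"{species}_{condition}_tex_{tex}"
            libs.append(
                Library(
                    library_id=library_id,
                    condition=condition,
                    tex_state=tex,
                    reads=_reads_from_counts(counts, cfg, library_id),
                )
            )
        out.libraries[species] = libs
    return out


def simulate(cfg: SimConfig) -> SimulationOutput:
    """Convenience: generate truth and libraries in one call."""
    return simulate_libraries(generate_truth(cfg), cfg)
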