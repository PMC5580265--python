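"""End-to-end orchestration of the comparative dRNA-seq analysis.

Per species: filter alignments, build normalized 5'-end coverage, call TSSs
per condition from the TEX(+)/TEX(-) pair, cluster (30 bp), unify across
conditions (35 bp window), classify against the ORF annotation. Across
species: detect single-copy orthologs, build codon and UTR alignments,
match positional orthologous TSSs per class, compute TSS-locus identities,
condition fold changes and the consistent extreme candidates, and produce
the conservation summary and hypothesis tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparative, differential, orthology, stats_report
from .annotation import GenomeAnnotation
from .config import CONDITIONS, PipelineConfig, TEX_MINUS, TEX_PLUS
from .coverage import CoverageTrack, Library, coverage_from_alignments, filter_alignments
from .tss_classification import classify_all
from .tss_inference import TssRecord, call_tss, cluster_tss, unify_conditions


@dataclass
class SpeciesResult:
    annotation: GenomeAnnotation
    tracks: list[CoverageTrack]
    tss: list[TssRecord] = field(default_factory=list)

    def track(self, condition: str, tex_state: str) -> CoverageTrack:
        for t in self.tracks:
            if t.condition == condition and t.tex_state == tex_state:
                return t
        raise KeyError((condition, tex_state))


@dataclass
class PipelineResult:
    species: dict[str, SpeciesResult]
    ortholog_pairs: list[orthology.OrthologPair]
    comparisons: pd.DataFrame
    consistency: pd.DataFrame
    class_counts: pd.DataFrame
    fisher: pd.DataFrame
    trend: dict[str, tuple[float, float, str]]
    wilcoxon: dict[str, tuple[float, str]]


def infer_species_tss(
    annotation: GenomeAnnotation,
    libraries: list[Library],
    config: PipelineConfig,
    rdna_regions: list[tuple[str, int, int]] | None = None,
) -> SpeciesResult:
    """Coverage, TSS calling, clustering, unification and classification
    for one species."""
    filtered = [
        Library(
            lib.library_id,
            lib.condition,
            lib.tex_state,
            filter_alignments(
                lib.reads,
                rdna_regions=rdna_regions,
                min_frac=config.min_aln_frac,
                max_mm=config.max_mismatches,
                max_evalue=config.max_evalue,
            ),
        )
        for lib in libraries
    ]
    tracks = coverage_from_alignments(filtered, annotation.replicon_lengths)
    result = SpeciesResult(annotation=annotation, tracks=tracks)
    per_condition: dict[str, list[TssRecord]] = {}
    tex_plus_tracks: dict[str, CoverageTrack] = {}
    for condition in CONDITIONS:
        plus = result.track(condition, TEX_PLUS)
        minus = result.track(condition, TEX_MINUS)
        tex_plus_tracks[condition] = plus
        called = call_tss(plus, minus, config.min_step, config.min_enrich)
        per_condition[condition] = cluster_tss(called, config.cluster_distance)
    unified = unify_conditions(per_condition, config.unify_window, tex_plus_tracks)
    result.tss = classify_all(unified, annotation, config.utr_threshold)
    return result


def species_tss_from_tracks(
    annotation: GenomeAnnotation,
    tracks: list[CoverageTrack],
    config: PipelineConfig,
) -> SpeciesResult:
    """Same as :func:`infer_species_tss` but starting from precomputed
    (already normalized) coverage tracks, e.g. read from BedGraph."""
    result = SpeciesResult(annotation=annotation, tracks=tracks)
    per_condition: dict[str, list[TssRecord]] = {}
    tex_plus_tracks: dict[str, CoverageTrack] = {}
    for condition in CONDITIONS:
        plus = result.track(condition, TEX_PLUS)
        minus = result.track(condition, TEX_MINUS)
        tex_plus_tracks[condition] = plus
        called = call_tss(plus, minus, config.min_step, config.min_enrich)
        per_condition[condition] = cluster_tss(called, config.cluster_distance)
    unified = unify_conditions(per_condition, config.unify_window, tex_plus_tracks)
    result.tss = classify_all(unified, annotation, config.utr_threshold)
    return result


def build_orthologs(
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> list[orthology.OrthologPair]:
    """Single-copy orthologs with codon and UTR alignments attached."""
    pairs = orthology.build_single_copy_orthologs(
        annotation_a.proteome(),
        annotation_b.proteome(),
        min_global_identity=config.min_global_identity,
        rng=rng,
    )
    cds_a = annotation_a.cds_sequences()
    cds_b = annotation_b.cds_sequences()
    nt_aligner = orthology.make_nucleotide_aligner()
    for pair in pairs:
        orthology.build_codon_alignment(pair, cds_a[pair.gene_a], cds_b[pair.gene_b])
        orthology.build_utr_alignment(
            pair, annotation_a, annotation_b, config.utr_threshold, nt_aligner
        )
    return pairs


def attach_fold_changes(comp: pd.DataFrame, tss_by_id_a, tss_by_id_b) -> pd.DataFrame:
    bl, tb = CONDITIONS

    def fc(tss_id, lookup):
        if tss_id is None or (isinstance(tss_id, float) and pd.isna(tss_id)):
            return None
        tss = lookup[tss_id]
        return differential.fold_change(
            tss.level_by_condition.get(bl, 0.0), tss.level_by_condition.get(tb, 0.0)
        )

    comp = comp.copy()
    comp["fc_a"] = [fc(t, tss_by_id_a) for t in comp["tss_a"]]
    comp["fc_b"] = [fc(t, tss_by_id_b) for t in comp["tss_b"]]
    return comp


def run_pipeline(
    annotations: dict[str, GenomeAnnotation],
    libraries: dict[str, list[Library]],
    config: PipelineConfig | None = None,
    rdna_regions: dict[str, list[tuple[str, int, int]]] | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Run the full two-species analysis.

    ``annotations`` and ``libraries`` are keyed by species name; the first
    key is species A throughout the outputs.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    names = list(annotations)
    if len(names) != 2:
        raise ValueError("exactly two species expected")
    species_results = {
        name: infer_species_tss(
            annotations[name],
            libraries[name],
            config,
            (rdna_regions or {}).get(name),
        )
        for name in names
    }
    return run_comparative(species_results, config, rng=rng)


def run_comparative(
    species_results: dict[str, SpeciesResult],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Cross-species half of the analysis, given per-species TSS sets."""
    name_a, name_b = list(species_results)
    res_a, res_b = species_results[name_a], species_results[name_b]
    pairs = build_orthologs(res_a.annotation, res_b.annotation, config, rng=rng)
    identities = {(p.gene_a, p.gene_b): p.protein_identity for p in pairs}
    results = comparative.compare_all(
        pairs,
        res_a.annotation,
        res_b.annotation,
        res_a.tss,
        res_b.tss,
        max_col_dist=config.max_col_dist,
        flank=config.locus_flank,
        utr_threshold=config.utr_threshold,
    )
    comp = comparative.results_to_frame(results, identities)
    tss_by_id_a = {t.tss_id: t for t in res_a.tss}
    tss_by_id_b = {t.tss_id: t for t in res_b.tss}
    comp = attach_fold_changes(comp, tss_by_id_a, tss_by_id_b)

    ortho_rows = comp[comp["pair_status"] == comparative.ORTHOLOG]
    consistency = differential.build_consistency_frame(
        ortho_rows, statistic=config.combine_statistic
    )
    consistency = differential.select_consistent_candidates(
        consistency, fraction=config.candidate_fraction
    )

    class_counts = stats_report.class_count_table(comp)
    fisher = stats_report.fisher_conservation_fdr(
        stats_report.conservation_tables(class_counts)
    )
    trend: dict[str, tuple[float, float, str]] = {}
    for tss_class in stats_report.TSS_CLASSES:
        bins = stats_report.similarity_trend_bins(comp, tss_class)
        try:
            trend[tss_class] = stats_report.trend_test_linear(bins)
        except ValueError:
            trend[tss_class] = (float("nan"), float("nan"), "undefined")
    wilcoxon: dict[str, tuple[float, str]] = {}
    for tss_class in stats_report.TSS_CLASSES:
        sub = ortho_rows[
            (ortho_rows["class"] == tss_class)
            & ortho_rows["locus_identity"].notna()
            & ortho_rows["protein_identity"].notna()
        ]
        if len(sub):
            wilcoxon[tss_class] = stats_report.wilcoxon_paired(
                sub["locus_identity"].to_numpy(), sub["protein_identity"].to_numpy()
            )
        else:
            wilcoxon[tss_class] = (float("nan"), "undefined")
    return PipelineResult(
        species=species_results,
        ortholog_pairs=pairs,
        comparisons=comp,
        consistency=consistency,
        class_counts=class_counts,
        fisher=fisher,
        trend=trend,
        wilcoxon=wilcoxon,
    )
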