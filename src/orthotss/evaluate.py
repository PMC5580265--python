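"""Scoring pipeline output against planted synthetic truth.

Used by the parameter-recovery checks: a planted TSS counts as recovered
when a called TSS sits on the same replicon and strand within a position
tolerance; a planted orthologous TSS pair counts as matched when the
comparative stage reports an ortholog pair of the planted class, for the
planted gene pair, with both positions within tolerance of the planted
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import SPECIES, SyntheticTruth
from .tss_inference import TssRecord


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_planted_pairs: int
    n_matched_pairs: int
    n_candidate_truth: int
    n_candidate_found: int
    max_column_distance: int

    @property
    def tss_recovery(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0

    @property
    def pair_recovery(self) -> float:
        return self.n_matched_pairs / self.n_planted_pairs if self.n_planted_pairs else 1.0


def tss_recovery_fraction(
    truth: SyntheticTruth, species: str, called: list[TssRecord], tolerance: int = 5
) -> tuple[int, int]:
    """(planted, recovered) counts for one species."""
    by_key: dict[tuple[str, str], list[int]] = {}
    for rec in called:
        by_key.setdefault((rec.replicon, rec.strand), []).append(rec.position)
    planted = truth.planted_for(species)
    recovered = 0
    for tss in planted:
        positions = by_key.get((tss.replicon, tss.strand), [])
        if any(abs(p - tss.position) <= tolerance for p in positions):
            recovered += 1
    return len(planted), recovered


def _planted_pairs(truth: SyntheticTruth):
    seen = set()
    for tss in truth.planted_tss:
        if tss.partner_id is None or tss.species != SPECIES[0]:
            continue
        partner = truth.by_id(tss.partner_id)
        key = (tss.truth_id, partner.truth_id)
        if key not in seen:
            seen.add(key)
            yield tss, partner


def pair_recovery(
    truth: SyntheticTruth, comp: pd.DataFrame, tolerance: int = 5
) -> tuple[int, int]:
    """(planted orthologous pairs, pairs matched by the pipeline)."""
    ortho = comp[comp["pair_status"] == "ortholog"]
    n_planted = n_matched = 0
    for tss_a, tss_b in _planted_pairs(truth):
        n_planted += 1
        rows = ortho[
            (ortho["class"] == tss_a.class_label)
            & (ortho["gene_a"] == tss_a.gene_id)
            & (ortho["gene_b"] == tss_b.gene_id)
        ]
        hit = (
            (rows["pos_a"] - tss_a.position).abs() <= tolerance
        ) & ((rows["pos_b"] - tss_b.position).abs() <= tolerance)
        if hit.any():
            n_matched += 1
    return n_planted, n_matched


def candidate_recovery(
    truth: SyntheticTruth, consistency: pd.DataFrame, comp: pd.DataFrame, tolerance: int = 5
) -> tuple[int, int]:
    """How many planted extreme-consistent pairs appear in the candidate set."""
    flagged = consistency[consistency["candidate"]]
    n_truth = len(truth.consistent_candidates)
    n_found = 0
    for id_a, id_b in truth.consistent_candidates:
        tss_a = truth.by_id(id_a)
        tss_b = truth.by_id(id_b)
        hit = (
            ((flagged["pos_a"] - tss_a.position).abs() <= tolerance)
            & ((flagged["pos_b"] - tss_b.position).abs() <= tolerance)
            & (flagged["gene_a"] == tss_a.gene_id)
            & (flagged["gene_b"] == tss_b.gene_id)
        )
        if hit.any():
            n_found += 1
    return n_truth, n_found


def score_run(truth: SyntheticTruth, result, tolerance: int = 5) -> RecoveryReport:
    """Full recovery report for a :class:`~orthotss.pipeline.PipelineResult`."""
    n_planted = n_recovered = 0
    for species in SPECIES:
        planted, recovered = tss_recovery_fraction(
            truth, species, result.species[species].tss, tolerance
        )
        n_planted += planted
        n_recovered += recovered
    n_pairs, n_matched = pair_recovery(truth, result.comparisons, tolerance)
    n_truth, n_found = candidate_recovery(
        truth, result.consistency, result.comparisons, tolerance
    )
    ortho = result.comparisons[result.comparisons["pair_status"] == "ortholog"]
    max_dist = int(ortho["column_distance"].max()) if len(ortho) else 0
    return RecoveryReport(
        n_planted=n_planted,
        n_recovered=n_recovered,
        n_planted_pairs=n_pairs,
        n_matched_pairs=n_matched,
        n_candidate_truth=n_truth,
        n_candidate_found=n_found,
        max_column_distance=max_dist,
    )
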