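"""TSS calling from TEX(+)/TEX(-) coverage, clustering, condition unification.

The caller is a documented stand-in for TSSpredator: position p is called
when the 5'-end coverage step relative to the immediately upstream position
reaches ``min_step`` (normalized units) and the TEX(+)/TEX(-) ratio, with a
pseudocount of 1 on both sides, reaches ``min_enrich``. TEX treatment
degrades processed (5'-monophosphate) ends, so a genuine primary 5' end is
both a coverage step and TEX-enriched.

Candidate positions are chain-linked into clusters (consecutive sorted
positions at most ``distance`` apart join the same cluster) and each cluster
is reduced to its highest-step member. TSS sets called per condition are
pooled and re-clustered with a 35 bp window; the surviving representative
carries the per-condition transcription level, read from each condition's
TEX(+) track at the representative position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import MINUS, PLUS
from .coverage import CoverageTrack


@dataclass
class TssRecord:
    """A called transcription start site.

    ``position`` is the 1-based coordinate of the transcript's first
    nucleotide; ``step_height`` the coverage increase over the upstream
    neighbour; ``enrichment`` the pseudocounted TEX(+)/TEX(-) ratio;
    ``level_by_condition`` the normalized TEX(+) 5'-end coverage at
    ``position`` per condition; ``class_set`` a subset of {g, a, i, n} after
    classification, with ``associated_orfs`` naming the ORF tied to each
    positional class.
    """

    tss_id: str
    replicon: str
    position: int
    strand: str
    step_height: float
    enrichment: float
    level_by_condition: dict[str, float] = field(default_factory=dict)
    class_set: frozenset = frozenset()
    associated_orfs: dict[str, str] = field(default_factory=dict)

    @property
    def class_label(self) -> str:
        """Set rendering, e.g. {g, i} -> 'gi', in canonical g/a/i order."""
        order = "gain"
        return "".join(c for c in order if c in self.class_set)


def call_tss(
    tex_plus: CoverageTrack,
    tex_minus: CoverageTrack,
    min_step: float = 5.0,
    min_enrich: float = 2.0,
) -> list[TssRecord]:
    """Call candidate TSS positions from one condition's TEX pair."""
    if set(tex_plus.data) != set(tex_minus.data):
        raise ValueError("TEX(+) and TEX(-) tracks cover different replicons/strands")
    out: list[TssRecord] = []
    for (replicon, strand), plus_cov in sorted(tex_plus.data.items()):
        minus_cov = tex_minus.data[(replicon, strand)]
        if plus_cov.shape != minus_cov.shape:
            raise ValueError(f"track shape mismatch on {replicon}{strand}")
        upstream = np.empty_like(plus_cov)
        if strand == PLUS:
            # replicon edge: no upstream position, step defined as 0
            upstream[0] = plus_cov[0]
            upstream[1:] = plus_cov[:-1]
        else:
            upstream[-1] = plus_cov[-1]
            upstream[:-1] = plus_cov[1:]
        step = plus_cov - upstream
        enrich = (plus_cov + 1.0) / (minus_cov + 1.0)
        called = np.flatnonzero((step >= min_step) & (enrich >= min_enrich))
        for idx in called:
            pos = int(idx) + 1
            out.append(
                TssRecord(
                    tss_id=f"{replicon}{strand}{pos}",
                    replicon=replicon,
                    position=pos,
                    strand=strand,
                    step_height=float(step[idx]),
                    enrichment=float(enrich[idx]),
                )
            )
    return out


def _chain_clusters(positions: np.ndarray, distance: int) -> list[np.ndarray]:
    """Indices of chain-linkage clusters over sorted positions."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > distance) + 1
    return np.split(np.arange(len(positions)), breaks)


def cluster_tss(tss: list[TssRecord], distance: int = 30) -> list[TssRecord]:
    """Reduce chain-linked clusters to their highest-step member.

    Consecutive sorted positions on the same (replicon, strand) that are at
    most ``distance`` apart join one cluster; ties on step height break
    toward the smaller coordinate.
    """
    out: list[TssRecord] = []
    groups: dict[tuple[str, str], list[TssRecord]] = {}
    for rec in tss:
        groups.setdefault((rec.replicon, rec.strand), []).append(rec)
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: r.position)
        positions = np.array([r.position for r in members])
        for cluster in _chain_clusters(positions, distance):
            best = max(
                (members[i] for i in cluster),
                key=lambda r: (r.step_height, -r.position),
            )
            out.append(best)
    out.sort(key=lambda r: (r.replicon, r.position, r.strand))
    return out


def unify_conditions(
    per_condition_tss: dict[str, list[TssRecord]],
    window: int = 35,
    tex_plus_by_condition: dict[str, CoverageTrack] | None = None,
) -> list[TssRecord]:
    """Merge per-condition TSS sets into one species-level set.

    Pooled TSSs are chain-clustered with ``window``; the highest-step member
    represents each cluster (ties: smaller coordinate). When TEX(+) tracks
    are supplied, ``level_by_condition[c]`` is filled with condition c's
    normalized TEX(+) coverage at the representative position (0 allowed for
    conditions in which the TSS was not detected). Idempotent: re-unifying
    the output changes nothing.
    """
    pooled = [rec for recs in per_condition_tss.values() for rec in recs]
    unified = cluster_tss(pooled, distance=window)
    out = []
    for i, rec in enumerate(unified):
        levels = dict(rec.level_by_condition)
        if tex_plus_by_condition is not None:
            for condition, track in tex_plus_by_condition.items():
                levels[condition] = track.at(rec.replicon, rec.strand, rec.position)
        out.append(replace(rec, tss_id=f"TSS{i + 1:05d}", level_by_condition=levels))
    return out
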