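"""Condition fold changes per TSS and consistent extreme-candidate selection.

The transcription fold change of a TSS is log2(level in the branchless
condition / level in the true-branching condition); TSSs lacking signal in
either condition are excluded rather than smoothed (no pseudocount). For an
orthologous TSS pair the two species' fold changes define a quadrant:
same-sign pairs (quadrants I and III) respond consistently to the
condition, and the candidates are the 5% of pairs with the most extreme
combined fold change among them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import CONDITION_BRANCHLESS, CONDITION_TRUE_BRANCHING

EXCLUDED = None


@dataclass
class FoldChangeRecord:
    tss_id: str
    level_branchless: float
    level_true_branching: float
    log2_fc: float


def fold_change(level_bl: float, level_tb: float) -> float | None:
    """log2(branchless / true-branching), or EXCLUDED (None) on zero levels."""
    if level_bl < 0 or level_tb < 0:
        raise ValueError("transcription levels must be non-negative")
    if level_bl == 0 or level_tb == 0:
        return EXCLUDED
    return math.log2(level_bl / level_tb)


def fold_change_for_tss(tss) -> FoldChangeRecord | None:
    bl = tss.level_by_condition.get(CONDITION_BRANCHLESS, 0.0)
    tb = tss.level_by_condition.get(CONDITION_TRUE_BRANCHING, 0.0)
    fc = fold_change(bl, tb)
    if fc is EXCLUDED:
        return None
    return FoldChangeRecord(tss.tss_id, bl, tb, fc)


def quadrant(fc_a: float, fc_b: float) -> str:
    """Quadrant of the (fc_a, fc_b) plane; axis points fall outside I."""
    if fc_a > 0 and fc_b > 0:
        return "I"
    if fc_a <= 0 and fc_b > 0:
        return "II"
    if fc_a > 0 and fc_b <= 0:
        return "IV"
    return "III"


def _combined(fc_a: float, fc_b: float, statistic: str) -> float:
    if statistic == "sum":
        return fc_a + fc_b
    if statistic == "min":
        return min(abs(fc_a), abs(fc_b)) * (1 if fc_a + fc_b >= 0 else -1)
    if statistic == "product":
        return fc_a * fc_b
    raise ValueError(f"unknown combine statistic {statistic!r}")


def build_consistency_frame(
    ortho_pairs: pd.DataFrame, statistic: str = "sum"
) -> pd.DataFrame:
    """Per orthologous-TSS-pair consistency records.

    Expects columns tss_a, tss_b, fc_a, fc_b (fold changes per species);
    rows with an undefined fold change are dropped. A physical TSS pair
    occurring under several classes is counted once (class labels joined).
    """
    if ortho_pairs.empty:
        cols = list(ortho_pairs.columns) or ["tss_a", "tss_b", "fc_a", "fc_b"]
        return pd.DataFrame(columns=cols + ["quadrant", "combined_score"])
    df = ortho_pairs.dropna(subset=["fc_a", "fc_b"]).copy()
    if df.empty:
        return pd.DataFrame(
            columns=list(ortho_pairs.columns) + ["quadrant", "combined_score", "candidate"]
        )
    if "class" in df.columns:
        classes = (
            df.groupby(["tss_a", "tss_b"])["class"]
            .apply(lambda s: "".join(sorted(set(s))))
            .rename("class")
        )
        df = (
            df.drop(columns="class")
            .drop_duplicates(subset=["tss_a", "tss_b"])
            .merge(classes, on=["tss_a", "tss_b"])
        )
    df["quadrant"] = [quadrant(a, b) for a, b in zip(df["fc_a"], df["fc_b"])]
    df["combined_score"] = [
        _combined(a, b, statistic) for a, b in zip(df["fc_a"], df["fc_b"])
    ]
    return df


def select_consistent_candidates(
    records: pd.DataFrame, fraction: float = 0.05
) -> pd.DataFrame:
    """Flag the ceil(fraction * n) most extreme same-sign pairs.

    n counts every record with both fold changes defined; eligibility
    requires a strict same-sign pair (quadrant I or III). Ranking is by
    |combined_score| descending with ties broken toward the smaller tss_a
    id, so the selection is deterministic. If fewer same-sign records exist
    than the quota, all of them are flagged.
    """
    df = records.copy()
    if df.empty:
        df["candidate"] = pd.Series(dtype=bool)
        return df
    n_total = len(df)
    quota = math.ceil(fraction * n_total)
    eligible = df[df["quadrant"].isin(["I", "III"])]
    chosen = (
        eligible.assign(_abs=eligible["combined_score"].abs())
        .sort_values(["_abs", "tss_a"], ascending=[False, True], kind="stable")
        .head(quota)
    )
    df["candidate"] = df.index.isin(chosen.index)
    return df
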