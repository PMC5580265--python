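"""Conservation summary tables and hypothesis tests.

Per TSS class (g, a, i) the summary counts all TSSs found in single-copy
orthologous genes of either species, how many of them have a positional
ortholog in the other species, and the mean number of TSSs per contributing
ortholog pair. Pairwise class conservation contrasts use Fisher's exact
test on ortholog/singleton counts with Benjamini-Hochberg correction over
the three comparisons; the dependence of TSS orthology on protein
similarity uses the Cochran-Armitage chi-square test for linear trend; and
TSS-locus vs protein conservation uses the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparative import ORTHOLOG

TSS_CLASSES = ("g", "a", "i")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def class_count_row(
    tss_class: str, n_tss: int, n_ortho_genes: int, n_ortho_tss: int
) -> dict:
    """Summary-row arithmetic from raw counts.

    mean TSS per ortholog pair is rounded to 2 decimals; percentages to the
    nearest integer, with the singleton percentage defined as the complement
    so the two always add to 100.
    """
    n_singleton = n_tss - n_ortho_tss
    pct_ortho = _round_half_up(100.0 * n_ortho_tss / n_tss) if n_tss else 0
    return {
        "class": tss_class,
        "n_tss": n_tss,
        "n_ortho_genes": n_ortho_genes,
        "mean_tss_per_pair": round(n_tss / n_ortho_genes, 2) if n_ortho_genes else 0.0,
        "n_ortho_tss": n_ortho_tss,
        "n_singleton": n_singleton,
        "pct_ortho": pct_ortho,
        "pct_singleton": 100 - pct_ortho if n_tss else 0,
    }


def class_count_table(comp: pd.DataFrame) -> pd.DataFrame:
    """Per-class conservation summary from comparative match results.

    ``comp`` is the match-result table (one row per orthologous TSS pair or
    singleton). An ortholog gene pair counts toward a class when it carries
    at least one TSS of the class in either species.
    """
    rows = []
    for tss_class in TSS_CLASSES:
        sub = comp[comp["class"] == tss_class] if len(comp) else comp
        if len(sub) == 0:
            rows.append(class_count_row(tss_class, 0, 0, 0))
            continue
        n_pairs = int((sub["pair_status"] == ORTHOLOG).sum())
        n_single = int((sub["pair_status"] != ORTHOLOG).sum())
        n_genes = sub.groupby(["gene_a", "gene_b"]).ngroups
        rows.append(
            class_count_row(tss_class, 2 * n_pairs + n_single, n_genes, 2 * n_pairs)
        )
    return pd.DataFrame(rows).set_index("class")


def conservation_tables(counts: pd.DataFrame) -> dict[str, np.ndarray]:
    """The three pairwise 2x2 tables (rows ortholog/singleton, cols classes)."""
    tables = {}
    for c1, c2 in (("g", "a"), ("g", "i"), ("a", "i")):
        tables[f"{c1}-{c2}"] = np.array(
            [
                [counts.loc[c1, "n_ortho_tss"], counts.loc[c2, "n_ortho_tss"]],
                [counts.loc[c1, "n_singleton"], counts.loc[c2, "n_singleton"]],
            ]
        )
    return tables


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    A zero row or column margin admits no association; p = 1 by convention.
    """
    table = np.asarray(table)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_conservation_fdr(tables: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided Fisher exact p per 2x2 table, BH-adjusted over the family.

    A table with a zero margin carries no information on association and is
    assigned p = 1 by convention. ``direction`` reports which column has the
    larger ortholog proportion (by the odds ratio sign).
    """
    names, ps, directions = [], [], []
    for name, table in tables.items():
        table = np.asarray(table)
        p = fisher_exact_p(table)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            direction = "none"
        else:
            odds = stats.fisher_exact(table, alternative="two-sided")[0]
            direction = "col1" if odds > 1 else ("col2" if odds < 1 else "none")
        names.append(name)
        ps.append(float(p))
        directions.append(direction)
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame(
        {"comparison": names, "p": ps, "q": qs, "direction": directions}
    ).set_index("comparison")


def trend_test_linear(
    bins: list[tuple[int, int]], scores: list[float] | None = None
) -> tuple[float, float, str]:
    """Cochran-Armitage chi-square test for linear trend in proportions.

    ``bins`` is an ordered list of (n_ortholog, n_total) per similarity bin;
    ``scores`` default to equally spaced 0, 1, 2, ... Returns (z, p,
    direction) with a two-sided normal p; direction is "increasing" or
    "decreasing" along the bin order, or "none" for a flat profile.
    """
    bins = [(int(x), int(n)) for x, n in bins]
    nonempty = [(i, x, n) for i, (x, n) in enumerate(bins) if n > 0]
    if len(nonempty) < 2:
        raise ValueError("trend test needs at least 2 non-empty bins")
    if any(x > n for _, x, n in nonempty):
        raise ValueError("bin count exceeds bin total")
    if scores is None:
        scores = list(range(len(bins)))
    s = np.array([scores[i] for i, _, _ in nonempty], dtype=float)
    x = np.array([x for _, x, _ in nonempty], dtype=float)
    n = np.array([n for _, _, n in nonempty], dtype=float)
    big_n = n.sum()
    p_bar = x.sum() / big_n
    t = float((s * x).sum() - p_bar * (s * n).sum())
    var = p_bar * (1 - p_bar) * float((s**2 * n).sum() - (s * n).sum() ** 2 / big_n)
    if var <= 0 or t == 0:
        return 0.0, 1.0, "none"
    z = t / math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p, "increasing" if z > 0 else "decreasing"


def similarity_trend_bins(
    comp: pd.DataFrame,
    tss_class: str,
    edges: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """(n_ortholog, n_total) per protein-identity bin for one class.

    Default bins are seven 10-point windows spanning 30-100% identity.
    """
    if edges is None:
        edges = np.arange(30.0, 101.0, 10.0)
    sub = comp[(comp["class"] == tss_class) & comp["protein_identity"].notna()]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = sub[(sub["protein_identity"] >= lo) & (sub["protein_identity"] < hi if hi < edges[-1] else sub["protein_identity"] <= hi)]
        n_orth = int((in_bin["pair_status"] == ORTHOLOG).sum())
        n_total = 2 * n_orth + int((in_bin["pair_status"] != ORTHOLOG).sum())
        out.append((2 * n_orth, n_total))
    return out


def wilcoxon_paired(x, y) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank p and direction for paired vectors.

    Zero differences are dropped; all-zero input gives p = 1 and no
    direction. The exact distribution is used for up to 25 informative
    pairs, the normal approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return 1.0, "none"
    method = "exact" if len(d) <= 25 else "approx"
    result = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    direction = "greater" if np.median(d) > 0 else ("less" if np.median(d) < 0 else "none")
    return float(result.pvalue), direction
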