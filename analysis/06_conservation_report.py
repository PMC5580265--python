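"""Conservation summary and hypothesis tests.

Builds the per-class conservation table (total TSSs in orthologous genes,
contributing gene pairs, orthologous vs lineage-specific TSSs), runs the
pairwise Fisher/BH class-conservation contrasts, the Cochran-Armitage trend
test of TSS orthology against protein-similarity bins, and the Wilcoxon
comparison of TSS-locus vs protein conservation. Writes everything under
results/report/.
"""

import json

from _common import load_stage, results_dir

from orthotss import stats_report


def main() -> None:
    comp = load_stage("comparisons")
    counts = stats_report.class_count_table(comp)
    fisher = stats_report.fisher_conservation_fdr(
        stats_report.conservation_tables(counts)
    )
    out = results_dir("report")
    counts.to_csv(out / "class_counts.tsv", sep="\t")
    fisher.to_csv(out / "fisher_fdr.tsv", sep="\t")
    print("per-class conservation summary:")
    print(counts.to_string())
    print("\npairwise class conservation (Fisher + BH):")
    print(fisher.to_string())

    tests = {}
    for cls in stats_report.TSS_CLASSES:
        bins = stats_report.similarity_trend_bins(comp, cls)
        try:
            z, p, direction = stats_report.trend_test_linear(bins)
            tests[f"trend_{cls}"] = {"z": z, "p": p, "direction": direction}
            print(f"\n{cls}TSS orthology vs protein similarity: "
                  f"z={z:.2f}, p={p:.3g} ({direction})")
        except ValueError as exc:
            tests[f"trend_{cls}"] = {"error": str(exc)}
            print(f"\n{cls}TSS trend test not defined here: {exc}")
        ortho = comp[(comp["class"] == cls) & (comp["pair_status"] == "ortholog")]
        ortho = ortho[ortho["locus_identity"].notna() & ortho["protein_identity"].notna()]
        if len(ortho):
            p, direction = stats_report.wilcoxon_paired(
                ortho["locus_identity"], ortho["protein_identity"]
            )
            tests[f"wilcoxon_{cls}"] = {"p": p, "direction": direction, "n": len(ortho)}
            print(f"{cls}TSS locus vs protein conservation (n={len(ortho)}): "
                  f"p={p:.3g}, locus identity {direction}")
    with open(out / "tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)
    print(f"\nreport -> {out}")


if __name__ == "__main__":
    main()
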