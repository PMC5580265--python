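"""Match positional orthologous TSSs between the species.

Relocates each TSS into its ortholog pair's UTR alignment (gTSS) or codon
alignment (aTSS/iTSS), pairs TSSs at most 35 alignment columns apart by
greedy nearest-first one-to-one matching, computes the +/-35 nt TSS-locus
identity for every matched pair, and attaches per-species condition fold
changes. Writes the match table under results/comparative/ and reports
per-class ortholog/singleton counts and pair recovery against the truth.
"""

from _common import load_stage, results_dir, save_stage

from orthotss import comparative
from orthotss.evaluate import pair_recovery
from orthotss.pipeline import attach_fold_changes
from orthotss.synthetic import SPECIES


def main() -> None:
    cfg, truth, sim = load_stage("world")
    config, species_results = load_stage("species_results")
    pairs = load_stage("orthologs")
    res_a = species_results[SPECIES[0]]
    res_b = species_results[SPECIES[1]]
    results = comparative.compare_all(
        pairs, res_a.annotation, res_b.annotation, res_a.tss, res_b.tss,
        max_col_dist=config.max_col_dist, flank=config.locus_flank,
        utr_threshold=config.utr_threshold,
    )
    identities = {(p.gene_a, p.gene_b): p.protein_identity for p in pairs}
    comp = comparative.results_to_frame(results, identities)
    comp = attach_fold_changes(
        comp, {t.tss_id: t for t in res_a.tss}, {t.tss_id: t for t in res_b.tss}
    )
    out = results_dir("comparative")
    comp.to_csv(out / "ortholog_tss.tsv", sep="\t", index=False)
    for cls in ("g", "a", "i"):
        sub = comp[comp["class"] == cls]
        n_pair = int((sub["pair_status"] == "ortholog").sum())
        n_single = len(sub) - n_pair
        print(f"{cls}TSS: {n_pair} orthologous pairs, {n_single} singletons")
    planted, matched = pair_recovery(truth, comp, tolerance=5)
    print(f"planted orthologous TSS pairs recovered: {matched}/{planted}")
    ortho = comp[comp["pair_status"] == "ortholog"]
    print(f"max column distance among matched pairs: {int(ortho['column_distance'].max())}")
    save_stage("comparisons", comp)
    print(f"match table -> {out}")


if __name__ == "__main__":
    main()
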