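"""Simulate the two-species dRNA-seq study design.

Generates two diverged genomes sharing 200 single-copy orthologous ORFs,
plants orthologous and lineage-specific TSSs of all positional classes
(including a small set of orthologous pairs with extreme, same-sign
condition fold changes), and emits TEX(+)/TEX(-) 5'-end libraries for the
branchless and true-branching conditions. Writes the ground truth and the
per-species genome/annotation files under results/simulated/.
"""

import argparse

from _common import results_dir, save_stage

from orthotss import io as oio
from orthotss.synthetic import SimConfig, generate_truth, simulate_libraries


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SimConfig(seed=args.seed)
    truth = generate_truth(cfg)
    sim = simulate_libraries(truth, cfg)

    out = results_dir("simulated")
    oio.write_truth_tables(truth, out / "truth")
    for species, ann in truth.genomes.items():
        oio.write_fasta(ann.replicons, out / f"{species}.genome.fasta")
        oio.write_fasta(ann.proteome(), out / f"{species}.proteins.fasta")
        oio.write_gff3(ann, out / f"{species}.gff3")

    n_pairs = sum(1 for t in truth.planted_tss if t.partner_id) // 2
    print(f"simulated 2 genomes of {len(truth.genomes['species_a'].replicons['chr']):,} nt "
          f"({cfg.n_ortholog_pairs} ortholog gene pairs, divergence {cfg.divergence})")
    print(f"planted {len(truth.planted_tss)} TSSs; {n_pairs} orthologous TSS pairs; "
          f"{len(truth.consistent_candidates)} extreme-consistent pairs")
    for species, libs in sim.libraries.items():
        sizes = ", ".join(f"{lib.library_id.split(species + '_')[1]}: {len(lib.reads):,}"
                          for lib in libs)
        print(f"{species} libraries ({sizes})")
    save_stage("world", (cfg, truth, sim))
    print(f"truth tables and genomes -> {out}")


if __name__ == "__main__":
    main()
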