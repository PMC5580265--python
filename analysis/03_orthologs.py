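"""Detect single-copy orthologous gene pairs between the two species.

Runs the reciprocal-best-hit search over the all-vs-all global alignment
score matrix (score floor calibrated on residue-shuffled pairs), applies
the single-copy and 30% global-identity filters, and attaches codon and UTR
alignments to each surviving pair. Writes the ortholog table under
results/orthology/.
"""

import numpy as np

from _common import load_stage, results_dir, save_stage

from orthotss import io as oio
from orthotss.pipeline import build_orthologs
from orthotss.synthetic import SPECIES


def main() -> None:
    cfg, truth, sim = load_stage("world")
    config, species_results = load_stage("species_results")
    ann_a = species_results[SPECIES[0]].annotation
    ann_b = species_results[SPECIES[1]].annotation
    pairs = build_orthologs(ann_a, ann_b, config, rng=np.random.default_rng(cfg.seed))
    out = results_dir("orthology")
    oio.write_ortholog_table(pairs, out / "ortholog_pairs.tsv")
    identities = [p.protein_identity for p in pairs]
    print(f"{len(pairs)} single-copy ortholog pairs "
          f"(of {cfg.n_ortholog_pairs} planted; protein identity "
          f"{min(identities):.1f}-{max(identities):.1f}%, "
          f"median {np.median(identities):.1f}%)")
    save_stage("orthologs", pairs)
    print(f"ortholog table -> {out}")


if __name__ == "__main__":
    main()
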