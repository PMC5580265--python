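"""Global alignment, RBBH single-copy orthologs, codon alignment maps."""

import numpy as np
import pytest

from orthotss.orthology import (
    AlignmentMap,
    OrthologPair,
    build_codon_alignment,
    build_single_copy_orthologs,
    codon_alignment_map,
    degap,
    global_align,
    make_nucleotide_aligner,
)
from orthotss.synthetic import SimConfig, generate_truth

RNG = np.random.default_rng(11)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(n=80, rng=RNG):
    return "".join(rng.choice(AA, size=n))


def mutated(seq, n_subs, rng=RNG):
    out = list(seq)
    for idx in rng.choice(len(seq), size=n_subs, replace=False):
        out[idx] = rng.choice([a for a in AA if a != out[idx]])
    return "".join(out)


class TestGlobalAlign:
    def test_identical_sequences(self):
        _, _, identity = global_align("MKLVINT", "MKLVINT")
        assert identity == 100.0

    def test_three_of_four_columns_match(self):
        row_a, row_b, identity = global_align("ACDE", "ACDF")
        assert (row_a, row_b) == ("ACDE", "ACDF")
        assert identity == 75.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")

    def test_nucleotide_alignment_degaps_to_inputs(self):
        aligner = make_nucleotide_aligner()
        a, b = "ACGTACGTACGT", "ACGTCGTACGTT"
        row_a, row_b, _ = global_align(a, b, aligner)
        assert degap(row_a) == a and degap(row_b) == b


class TestSingleCopyOrthologs:
    def _proteomes(self):
        base = [random_protein(90) for _ in range(3)]
        prot_a = {f"a{i}": seq for i, seq in enumerate(base)}
        prot_b = {f"b{i}": mutated(seq, 6) for i, seq in enumerate(base)}
        return prot_a, prot_b

    def test_mutual_best_hits_pair_up(self):
        prot_a, prot_b = self._proteomes()
        pairs = build_single_copy_orthologs(prot_a, prot_b, rng=np.random.default_rng(0))
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("a0", "b0"), ("a1", "b1"), ("a2", "b2")}
        assert all(p.protein_identity > 85 for p in pairs)

    def test_duplicated_gene_breaks_single_copy(self):
        prot_a, prot_b = self._proteomes()
        prot_a["a0_dup"] = prot_a["a0"]  # identical duplicate ties as best hit of b0
        pairs = build_single_copy_orthologs(prot_a, prot_b, rng=np.random.default_rng(0))
        genes_b = {p.gene_b for p in pairs}
        assert "b0" not in genes_b
        assert genes_b == {"b1", "b2"}

    def test_gene_without_credible_hit_stays_unpaired(self):
        prot_a, prot_b = self._proteomes()
        prot_a["a3"] = random_protein(90)  # unrelated to everything in b
        pairs = build_single_copy_orthologs(prot_a, prot_b, rng=np.random.default_rng(0))
        assert "a3" not in {p.gene_a for p in pairs}
        assert len(pairs) == 3

    def test_symmetric_in_species_order(self):
        prot_a, prot_b = self._proteomes()
        fwd = build_single_copy_orthologs(prot_a, prot_b, rng=np.random.default_rng(0))
        rev = build_single_copy_orthologs(prot_b, prot_a, rng=np.random.default_rng(0))
        assert {(p.gene_a, p.gene_b) for p in fwd} == {(p.gene_b, p.gene_a) for p in rev}

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError):
            build_single_copy_orthologs({"x": "MKL"}, {"x": "MKL", "y": "MKV"},
                                        score_threshold=0.0)


class TestCodonAlignment:
    def test_gap_expansion(self):
        # protein alignment AC-D / ACED: 12 codon columns, columns 7-9 gapped in row 1
        pair = OrthologPair("ga", "gb", 75.0, ("AC-D", "ACED"))
        cds_a = "GCATGTGAT"          # A  C  D
        cds_b = "GCATGTGAAGAT"       # A  C  E  D
        build_codon_alignment(pair, cds_a, cds_b)
        assert pair.codon_alignment == ("GCATGT---GAT", "GCATGTGAAGAT")
        assert len(pair.codon_alignment[0]) == 3 * 4

    def test_degapping_recovers_cds(self):
        pair = OrthologPair("ga", "gb", 75.0, ("AC-D", "ACED"))
        build_codon_alignment(pair, "GCATGTGAT", "GCATGTGAAGAT")
        assert degap(pair.codon_alignment[0]) == "GCATGTGAT"
        assert degap(pair.codon_alignment[1]) == "GCATGTGAAGAT"

    def test_length_mismatch_errors(self):
        pair = OrthologPair("ga", "gb", 75.0, ("AC-D", "ACED"))
        with pytest.raises(ValueError):
            build_codon_alignment(pair, "GCATGT", "GCATGTGAAGAT")

    def test_map_round_trip(self):
        pair = OrthologPair("ga", "gb", 75.0, ("AC-D", "ACED"))
        build_codon_alignment(pair, "GCATGTGAT", "GCATGTGAAGAT")
        map_a, map_b = codon_alignment_map(pair)
        # ungapped alignment row: position k <-> column k
        assert [map_b.column(k) for k in range(1, 13)] == list(range(1, 13))
        # gapped row skips the gap columns
        assert [map_a.column(k) for k in range(1, 10)] == [1, 2, 3, 4, 5, 6, 10, 11, 12]
        for col in range(1, 13):
            pos = map_a.position(col)
            if pos is not None:
                assert map_a.column(pos) == col


class TestAlignmentMap:
    def test_gap_columns_have_no_position(self):
        m = AlignmentMap("AC--GT")
        assert m.position(3) is None and m.position(4) is None
        assert m.ungapped_length == 4
        with pytest.raises(IndexError):
            m.column(5)


def test_mean_identity_decreases_with_divergence():
    means = []
    for divergence in (0.0, 0.05, 0.1, 0.2):
        truth = generate_truth(
            SimConfig(n_ortholog_pairs=25, n_lineage_specific_tss=0,
                      divergence=divergence, seed=5)
        )
        means.append(np.mean([f for _, _, f in truth.ortholog_gene_pairs]))
    assert means[0] == 1.0
    assert all(a > b for a, b in zip(means, means[1:]))
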