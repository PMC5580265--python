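"""The synthetic two-species world: determinism, planted structure, noise model."""

import math

import numpy as np
import pandas as pd
import pytest

from orthotss.config import CONDITIONS, ConfigError, TEX_MINUS, TEX_PLUS
from orthotss.synthetic import (
    REPLICON,
    SPECIES,
    SimConfig,
    expected_intensity,
    generate_truth,
    simulate_libraries,
)

BL, TB = CONDITIONS


def small_cfg(**kw):
    base = dict(n_ortholog_pairs=12, n_lineage_specific_tss=6, seed=42)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_world_exactly(self):
        t1 = generate_truth(small_cfg())
        t2 = generate_truth(small_cfg())
        assert t1.genomes[SPECIES[0]].replicons == t2.genomes[SPECIES[0]].replicons
        assert t1.genomes[SPECIES[1]].replicons == t2.genomes[SPECIES[1]].replicons
        assert [
            (p.truth_id, p.position, p.strand, p.class_label, p.partner_id)
            for p in t1.planted_tss
        ] == [
            (p.truth_id, p.position, p.strand, p.class_label, p.partner_id)
            for p in t2.planted_tss
        ]
        s1 = simulate_libraries(t1, small_cfg())
        s2 = simulate_libraries(t2, small_cfg())
        for species in SPECIES:
            for l1, l2 in zip(s1.libraries[species], s2.libraries[species]):
                pd.testing.assert_frame_equal(l1.reads, l2.reads)

    def test_different_seed_differs(self):
        t1 = generate_truth(small_cfg())
        t2 = generate_truth(small_cfg(seed=43))
        assert t1.genomes[SPECIES[0]].replicons != t2.genomes[SPECIES[0]].replicons


class TestTruthStructure:
    def test_zero_divergence_means_identical_proteins(self):
        truth = generate_truth(small_cfg(divergence=0.0))
        assert all(f == 1.0 for _, _, f in truth.ortholog_gene_pairs)

    def test_partner_references_are_reciprocal(self):
        truth = generate_truth(small_cfg())
        for tss in truth.planted_tss:
            if tss.partner_id is not None:
                partner = truth.by_id(tss.partner_id)
                assert partner.partner_id == tss.truth_id
                assert partner.species != tss.species
                assert partner.class_label == tss.class_label

    def test_positions_inside_replicon(self):
        truth = generate_truth(small_cfg())
        for tss in truth.planted_tss:
            length = len(truth.genomes[tss.species].replicons[tss.replicon])
            assert 1 <= tss.position <= length

    def test_consistent_candidates_have_same_sign_extreme_fold_changes(self):
        truth = generate_truth(small_cfg(n_ortholog_pairs=40, planted_extreme_fraction=0.2))
        assert truth.consistent_candidates
        for id_a, id_b in truth.consistent_candidates:
            fcs = []
            for tid in (id_a, id_b):
                tss = truth.by_id(tid)
                assert tss.is_extreme
                assert tss.level_by_condition[BL] > 0 and tss.level_by_condition[TB] > 0
                fcs.append(math.log2(tss.level_by_condition[BL] / tss.level_by_condition[TB]))
            assert fcs[0] * fcs[1] > 0

    def test_ortho_fraction_within_binomial_ci(self):
        cfg = SimConfig(n_ortholog_pairs=200, n_lineage_specific_tss=0,
                        fraction_ortho_tss=0.5, seed=7)
        truth = generate_truth(cfg)
        partnered = sum(1 for t in truth.planted_tss if t.partner_id is not None)
        n_events = partnered // 2 + (len(truth.planted_tss) - partnered) // 2
        frac = partnered / len(truth.planted_tss)
        half_width = 2.576 * math.sqrt(0.25 / n_events)
        assert abs(frac - 0.5) <= half_width

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            generate_truth(small_cfg(fraction_ortho_tss=1.5))
        with pytest.raises(ConfigError):
            SimConfig(tex_enrichment=0.5).validate()


class TestLibrarySimulation:
    def test_zero_noise_limit_reproduces_planted_profile(self):
        cfg = small_cfg(background_noise_rate=0.0, jitter_sd=0.0, poisson=False,
                        tex_enrichment=float("inf"), fc_log2_sd=0.0,
                        planted_extreme_fraction=0.0)
        truth = generate_truth(cfg)
        sim = simulate_libraries(truth, cfg)
        lib = sim.library(SPECIES[0], BL, TEX_PLUS)
        # TEX(+) 5' ends sit exactly at planted positions with planted heights
        counts = lib.reads.groupby(["strand", "start"]).size()
        planted = {
            (t.strand, t.position): t.level_by_condition[BL]
            for t in truth.planted_for(SPECIES[0])
        }
        for (strand, start), n in counts.items():
            pos = start if strand == "+" else int(
                lib.reads[(lib.reads["strand"] == strand) & (lib.reads["start"] == start)]["end"].iloc[0]
            )
            assert (strand, pos) in planted
            assert n == round(planted[(strand, pos)])
        # TEX(-) is empty: infinite enrichment leaves no processed signal
        assert sim.library(SPECIES[0], BL, TEX_MINUS).reads.empty

    def test_fixed_library_sizes_are_exact(self):
        cfg = small_cfg(library_sizes=[1000, 1000, 1000, 1000])
        sim = simulate_libraries(generate_truth(cfg), cfg)
        for species in SPECIES:
            for lib in sim.libraries[species]:
                assert len(lib.reads) == 1000

    def test_tex_minus_depleted_tenfold_in_expectation(self):
        """Planted height 50, enrichment 10 -> mean TEX(-) signal ~5 at the TSS."""
        base = dict(n_ortholog_pairs=3, n_lineage_specific_tss=0,
                    step_height_range=(50.0, 50.0), fc_log2_sd=0.0,
                    planted_extreme_fraction=0.0, background_noise_rate=0.0,
                    jitter_sd=0.0, tex_enrichment=10.0)
        truth = generate_truth(SimConfig(seed=1, **base))
        values = []
        for seed in range(100):
            sim = simulate_libraries(truth, SimConfig(seed=seed, **base))
            lib = sim.library(SPECIES[0], BL, TEX_MINUS)
            counts = lib.reads.groupby(["strand", "start", "end"]).size()
            per_tss = {}
            for (strand, start, end), n in counts.items():
                pos = start if strand == "+" else end
                per_tss[(strand, pos)] = n
            for t in truth.planted_for(SPECIES[0]):
                values.append(per_tss.get((t.strand, t.position), 0))
        assert np.mean(values) == pytest.approx(5.0, abs=0.5)

    def test_expected_intensity_places_mass_at_planted_positions(self):
        cfg = small_cfg(jitter_sd=1.0, jitter_max=2)
        truth = generate_truth(cfg)
        lam = expected_intensity(truth, cfg, SPECIES[0], BL, TEX_PLUS)
        for t in truth.planted_for(SPECIES[0]):
            arr = lam[(t.replicon, t.strand)]
            window = arr[t.position - 3 : t.position + 2]
            assert window.sum() == pytest.approx(
                t.level_by_condition[BL] + 5 * cfg.background_noise_rate
            )
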