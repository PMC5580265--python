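import numpy as np
import pytest
from hypothesis import settings

from orthotss.annotation import GenomeAnnotation, OrfRecord
from orthotss.pipeline import run_pipeline
from orthotss.synthetic import SPECIES, SimConfig, generate_truth, simulate_libraries

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_annotation(orf_specs, length=2000, species="test", seed=0):
    """Annotation with random sequence and ORFs given as (start, end, strand)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    orfs = [
        OrfRecord(f"{species}_g{i:02d}", "chr", start, end, strand)
        for i, (start, end, strand) in enumerate(orf_specs)
    ]
    return GenomeAnnotation(species, {"chr": seq}, orfs)


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated two-species world plus the full pipeline result."""
    cfg = SimConfig(n_ortholog_pairs=30, n_lineage_specific_tss=15, seed=3)
    truth = generate_truth(cfg)
    sim = simulate_libraries(truth, cfg)
    result = run_pipeline(
        {s: truth.genomes[s] for s in SPECIES},
        sim.libraries,
        rng=np.random.default_rng(7),
    )
    return cfg, truth, sim, result
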