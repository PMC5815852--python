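import numpy as np
import pytest

from repeatrain import (
    AssignParams,
    FamilySpec,
    RepeatAnnotation,
    SimulationConfig,
    build_combined_reference,
    default_config,
    generate_genome,
    generate_reads,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact two-satellite / one-SINE world, error-free, no decoy genes."""
    return SimulationConfig(
        seed=42,
        contig_lengths=[30_000, 20_000],
        repeat_families=[
            FamilySpec("GSAT-like", 200, 12, divergence=0.02, tandem=True,
                       baseline_expression=1.0, strand_symmetric=True),
            FamilySpec("SATMIN-like", 120, 10, divergence=0.02, tandem=True,
                       baseline_expression=0.3, strand_symmetric=True),
            FamilySpec("SINE-B1-like", 150, 12, divergence=0.08,
                       baseline_expression=1.0),
        ],
        n_background_genes=6,
        background_expression=4.0,
        reads_per_sample=2_000,
        error_rate=0.0,
        sine_embed_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, ann = generate_genome(small_config)
    ref = build_combined_reference(ann, genome, small_config.read_length)
    reads, truth = generate_reads(genome, ann, small_config)
    return {"config": small_config, "genome": genome, "annotation": ann,
            "ref": ref, "reads": reads, "truth": truth}


@pytest.fixture()
def toy_ref():
    """Hand-built reference: two unrelated families, no instances, tiny mask."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    fam_a = "".join(rng.choice(bases, 80))
    fam_b = "".join(rng.choice(bases, 80))
    genome = {"ctg": "".join(rng.choice(bases, 400))}
    ann = RepeatAnnotation(families={"famA": fam_a, "famB": fam_b}, instances=[])
    return build_combined_reference(ann, genome, 26)


@pytest.fixture()
def default_params():
    return AssignParams()
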