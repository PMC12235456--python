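import numpy as np
import pytest

from scari import (
    PipelineConfig,
    ScoringScheme,
    SimConfig,
    SpeciesInput,
    simulate_cluster,
)

TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t1000\t2000\t.\t+\t.\tID=RBP5;Name=RBP5
chr1\ttoy\tgene\t3000\t4000\t.\t+\t.\tID=CLSTN3;Name=CLSTN3
chr1\ttoy\tgene\t5000\t6000\t.\t+\t.\tID=PEX5;Name=PEX5
chr1\ttoy\tgene\t7000\t8000\t.\t+\t.\tID=G1
chr1\ttoy\tgene\t9000\t10000\t.\t-\t.\tID=G2
chr1\ttoy\tgene\t11000\t12000\t.\t+\t.\tID=G3
chr1\ttoy\tgene\t13000\t14000\t.\t+\t.\tID=CLEC4E;Name=CLEC4E
chr1\ttoy\tgene\t15000\t16000\t.\t+\t.\tID=CLEC4D;Name=CLEC4D
chr1\ttoy\tgene\t17000\t18000\t.\t+\t.\tID=CLEC6A;Name=CLEC6A
"""


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture
def toy_gff3() -> str:
    return TOY_GFF3


@pytest.fixture(scope="session")
def sim_no_events():
    """One simulated dataset with no duplications or losses."""
    return simulate_cluster(SimConfig(seed=42, dup_rate=0.0, loss_rate=0.0))


def pipeline_config_for(sim, seed=0, **kwargs) -> PipelineConfig:
    return PipelineConfig(
        species={
            s: SpeciesInput(
                gff3=sim.gff3[s], fasta=sim.fasta[s],
                chromosomes=tuple(sim.chromosomes[s]),
            )
            for s in sim.gff3
        },
        reference_species="cattle",
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
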