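import numpy as np
import pytest

from cyanohg import core_io, synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hgl_panel_def():
    return core_io.load_panel("hgl")


@pytest.fixture(scope="session")
def nif_panel_def():
    return core_io.load_panel("nif")


@pytest.fixture(scope="session")
def planted_sim(hgl_panel_def):
    """One genome with a full 19-gene island at 70% identity + 50 decoys."""
    config = synthgen.GenomeSimConfig(
        seed=7,
        n_genomes=1,
        decoy_count=50,
        panel_labels=tuple(hgl_panel_def.labels),
        planted={0: [synthgen.PlantedIslandSpec(tuple(hgl_panel_def.labels), identity=0.70)]},
    )
    return synthgen.simulate_genomes(config)


def make_genome(ordinals, contig="c1", genome_id="g1", n_orfs=None, protein="MKLV"):
    """Minimal genome whose ORFs occupy consecutive ordinals 0..n-1."""
    n = n_orfs if n_orfs is not None else (max(ordinals) + 5 if ordinals else 5)
    orfs = [
        core_io.OrfRecord(
            orf_id=f"orf{i}",
            contig_id=contig,
            ordinal=i,
            start=1 + 1000 * i,
            end=900 + 1000 * i,
            strand="+",
            protein=protein,
        )
        for i in range(n)
    ]
    return core_io.GenomeRecord(genome_id, [core_io.ContigInfo(contig, 1000 * n)], orfs)
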