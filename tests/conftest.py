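import numpy as np
import pytest

from methylfree import simulate
from methylfree.genome import GeneModel, GenomeSequence, TEAnnotation

CATS = ("gbM", "Intron-teM", "Other-teM", "pM", "dM", "UM")


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic 10-kb chromosome plus a 2-kb organelle control."""
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chr1 = bases[rng.integers(0, 4, 10_000)].tobytes().decode()
    chrc = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
    return GenomeSequence({"c1": chr1, "ChrC": chrc}, organelle_flags={"ChrC"})


@pytest.fixture(scope="session")
def small_config():
    """Small full-study configuration used for pipeline-level tests."""
    return simulate.SimulationConfig(
        seed=11,
        n_genes_per_category={c: 8 for c in CATS},
        n_per_pattern={p: 2 for p in simulate.PATTERN_EFFECTS},
        insertion_zone_len=40_000,
        n_background_pairs=60,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, genes, tes, truth = simulate.simulate_genome(small_config)
    return {"genome": genome, "genes": genes, "tes": tes, "truth": truth, "config": small_config}


def make_gene(gene_id="g1", chrom="c1", strand="+", start=5001, end=6000, exons=None):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=tuple(exons) if exons else ((start, end),),
    )


def make_te(te_id="te1", family="FAM1", chrom="c1", strand="+", start=1001, end=2000):
    return TEAnnotation(te_id=te_id, family=family, chrom=chrom, strand=strand, start=start, end=end)
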