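import numpy as np
import pytest

from vartig.alphabet import AA, BACKGROUND
from vartig.cogs import Msa, SequenceRecord
from vartig.simulate import SimConfig, simulate_species_tree, simulate_vartig_proteins


def random_protein(rng, n: int) -> str:
    return "".join(AA[i] for i in rng.choice(20, size=n, p=BACKGROUND))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def species_tree_8():
    return simulate_species_tree(8, seed=11)


@pytest.fixture(scope="session")
def vartig_dataset(species_tree_8):
    """Simulated modular proteins with heavy C-terminal shuffling."""
    cfg = SimConfig(n_genomes=8, cterm_pool_size=6, recomb_prob=0.8, seed=11)
    records, aln, truth = simulate_vartig_proteins(
        species_tree_8, cfg, rng=np.random.default_rng(11)
    )
    return {"tree": species_tree_8, "cfg": cfg, "records": records,
            "alignment": aln, "truth": truth}


def msa_from_strings(*seqs, genomes=None) -> Msa:
    genomes = genomes or ["g"] * len(seqs)
    return Msa(rows=[(f"r{i}", genomes[i], s) for i, s in enumerate(seqs)])


def records_from_strings(*seqs, genomes=None):
    genomes = genomes or ["g"] * len(seqs)
    return [SequenceRecord(f"r{i}", genomes[i], s) for i, s in enumerate(seqs)]
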