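import numpy as np
import pytest

from dockconsensus.synthetic_data import (
    DecoyLadderSpec,
    ScoreModelSpec,
    ToyComplexSpec,
    assign_scores,
    generate_decoy_ladder,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy():
    """Default planted-interface toy complex (dimeric receptor)."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def toy_monomer():
    """Single-chain receptor variant."""
    return make_toy_complex(ToyComplexSpec(homodimer=False))


@pytest.fixture(scope="session")
def small_ladder(toy):
    """Small decoy ladder with two pseudo-method score columns."""
    spec = DecoyLadderSpec(rungs=(1.0, 2.0, 5.0, 10.0, 20.0),
                           decoys_per_rung=30, n_random=60, seed=7)
    decoys, truth = generate_decoy_ladder(toy, spec)
    err = truth["true_ligand_rmsd"]
    assign_scores(decoys, ScoreModelSpec(name="rigid_like", correlation=0.8,
                                         seed=71), err)
    assign_scores(decoys, ScoreModelSpec(name="guided_like", correlation=0.8,
                                         seed=72), err)
    return decoys, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
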