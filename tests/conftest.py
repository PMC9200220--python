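import pathlib

import numpy as np
import pytest

from vscreen import chem_features as cf

DATA_DIR = pathlib.Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> pathlib.Path:
    return DATA_DIR


def make_table_for(smiles_list, dim=300, seed=0, radii=cf.DEFAULT_RADII) -> cf.EmbeddingTable:
    """Random embedding table covering every token of the given molecules."""
    tokens = set()
    for smi in smiles_list:
        tokens |= set(cf.smiles_to_sentence(smi, radii=radii).tokens)
    rng = np.random.default_rng(seed)
    vectors = {t: rng.standard_normal(dim) for t in sorted(tokens)}
    return cf.EmbeddingTable(dim=dim, vectors=vectors, unk_vector=rng.standard_normal(dim))


@pytest.fixture(scope="session")
def small_table() -> cf.EmbeddingTable:
    return make_table_for(
        ["C", "CC", "CCO", "CCN", "c1ccccc1", "CC(=O)O", "CN", "O", "N"], seed=7
    )
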