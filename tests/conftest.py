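import numpy as np
import pytest

from lpipredict import InteractionDataset, SimilarityMatrix


def random_similarity(k: int, rng: np.random.Generator,
                      kind: str = "lncrna") -> SimilarityMatrix:
    """A valid random similarity matrix (symmetric, unit diagonal, [0,1])."""
    M = rng.random((k, k))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    ids = [f"{'lnc' if kind == 'lncrna' else 'prot'}{i}" for i in range(k)]
    return SimilarityMatrix(ids, M, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset():
    """4x3 dataset with min degree 2 on both axes (LOOCV-ready)."""
    Y = np.array([
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
    ], dtype=float)
    return InteractionDataset([f"lnc{i}" for i in range(4)],
                              [f"prot{j}" for j in range(3)], Y)


@pytest.fixture
def tiny_sims(tiny_dataset):
    r = np.random.default_rng(7)
    lnc = random_similarity(4, r, "lncrna")
    prot = random_similarity(3, r, "protein")
    lnc.ids = list(tiny_dataset.lnc_ids)
    prot.ids = list(tiny_dataset.prot_ids)
    return lnc, prot
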