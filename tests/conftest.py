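import numpy as np
import pytest

from sumosite import (
    LabeledDataset,
    MotifModel,
    PeptideWindow,
    Protein,
    SyntheticDatasetSpec,
    generate_peptides,
)


@pytest.fixture(scope="session")
def small_motif_dataset() -> LabeledDataset:
    """300/class, L=21 planted-motif dataset for fast model-level tests."""
    spec = SyntheticDatasetSpec(300, 300, MotifModel(L=21, seed=11))
    return generate_peptides(spec)


@pytest.fixture()
def toy_proteins() -> list[Protein]:
    return [
        Protein("P1", "MKAKLLVEDKAAKWWK"),
        Protein("P2", "AAAACDEFGHIK"),
    ]


def make_window(seq: str, label=None) -> PeptideWindow:
    return PeptideWindow("T", len(seq) // 2 + 1, seq, label)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
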