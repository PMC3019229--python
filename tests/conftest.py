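import numpy as np
import pytest

from mirsvm import MicroRNA, SyntheticConfig, Transcript, generate_dataset, train_two_step


@pytest.fixture(scope="session")
def mir21() -> MicroRNA:
    # hsa-miR-21; seed 2-8 = AGCUUAU.
    return MicroRNA(id="mir21", sequence="UAGCUUAUCAGACUGAUGUUGA")


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGU")), size=length))


def random_mirna(rng, ident: str = "mir", length: int = 22) -> MicroRNA:
    while True:
        seq = random_rna(rng, length)
        if "U" in seq[1:8] and "G" in seq[1:8]:
            return MicroRNA(id=ident, sequence=seq)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic transfection-style dataset shared across tests."""
    cfg = SyntheticConfig(n_mirnas=3, n_transcripts=300, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_train(small_dataset):
    """Two-step training on the small dataset (5 folds for speed)."""
    ds = small_dataset
    return train_two_step(
        ds.mirnas, ds.transcripts, ds.labels, k=5, seed=11, negative_cap=600
    )
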