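import numpy as np
import pytest

from ptmsvm.kernels import InteractionProfileMatrix
from ptmsvm.synthetic import MotifSpec, NetworkSpec, full_consensus, generate_dataset
from ptmsvm.windows import STANDARD_AA, PeptideWindow


def random_windows(n: int, seed: int, length: int = 21) -> list[PeptideWindow]:
    """Random peptide windows over the 20 standard residues, centre forced to S/T/Y."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    centres = np.array(list("STY"))
    out = []
    for i in range(n):
        chars = rng.choice(letters, size=length)
        chars[length // 2] = rng.choice(centres)
        out.append(PeptideWindow(f"w{i:04d}:11", "".join(chars)))
    return out


def random_profiles(n: int, n_ptms: int, seed: int) -> InteractionProfileMatrix:
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n_ptms)) < 0.4).astype(np.int8)
    return InteractionProfileMatrix(
        [f"w{i:04d}:11" for i in range(n)],
        [f"ptm{j}" for j in range(n_ptms)],
        A,
    )


@pytest.fixture(scope="session")
def strong_dataset():
    """A small dataset with clear sequence and network signal."""
    motif = MotifSpec(consensus=full_consensus("S"), match_prob=0.9)
    network = NetworkSpec(n_ptms=8, co_occurrence_prob=0.6, background_prob=0.05)
    return generate_dataset(40, 40, motif, network, seed=11)


@pytest.fixture(scope="session")
def null_dataset():
    """A dataset with no class signal in either view."""
    motif = MotifSpec(consensus=full_consensus("S"), match_prob=0.05)
    network = NetworkSpec(n_ptms=8, co_occurrence_prob=0.05, background_prob=0.05)
    return generate_dataset(40, 40, motif, network, seed=12)
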