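import numpy as np
import pytest

from motuinv.io import Alignment, SequenceRecord


def make_alignment(seqs: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in seqs.items()])


def random_alignment(rng: np.random.Generator, n: int, length: int) -> Alignment:
    bases = np.array(list("ACGT"))
    return Alignment(
        [
            SequenceRecord(f"t{i:02d}", "".join(bases[rng.integers(0, 4, length)]))
            for i in range(n)
        ]
    )


def random_binary_tree(rng: np.random.Generator, labels: list[str]) -> str:
    """Random binary newick over the given labels (random joins)."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
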