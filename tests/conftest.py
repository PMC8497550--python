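import numpy as np
import pytest

from triproj.data_io import AlignedTriple, BipartiteNetwork
from triproj.latent_factor import ScoreMatrix
from triproj.synthetic_data import SyntheticConfig, generate


@pytest.fixture
def tiny_triple():
    """2 lncRNAs x 2 miRNAs x 2 diseases, hand-checkable."""
    lm = BipartiteNetwork(["L1", "L2"], ["M1", "M2"], [[1, 1], [0, 1]])
    md = BipartiteNetwork(["M1", "M2"], ["D1", "D2"], [[1, 0], [1, 1]])
    return AlignedTriple(lm, md)


@pytest.fixture(scope="session")
def planted():
    """Default planted-module fixture (m=60, n=30, e=40, g=3, seed=0)."""
    return generate(SyntheticConfig())


@pytest.fixture
def edge_file(tmp_path):
    """Write lines to a temp file and return its path."""

    def _write(lines, name="edges.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def random_scores(rng, m=4, e=3, stage="final"):
    return ScoreMatrix(
        [f"L{i}" for i in range(m)],
        [f"D{j}" for j in range(e)],
        rng.normal(size=(m, e)),
        stage=stage,
    )


def brute_force_auc(scores_flat, labels_flat):
    """Exhaustive Mann-Whitney: fraction of (pos, neg) pairs correctly
    ordered, ties counting 1/2.  Independent oracle for ranking AUC."""
    pos = scores_flat[labels_flat == 1]
    neg = scores_flat[labels_flat == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
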