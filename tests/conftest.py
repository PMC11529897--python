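import numpy as np
import pytest

from beetlegan import ClassLabel, FieldScores, MultispectralCrop, TreeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_crop(label: int, tree_id: str = "t", size: int = 8,
              fill: float = 0.5) -> MultispectralCrop:
    """A small constant crop; dataset-level ops are size-agnostic."""
    return MultispectralCrop(np.full((size, size, 5), fill), tree_id,
                             ClassLabel(label))


def make_crops(counts, size: int = 8):
    crops = []
    for label, n in enumerate(counts):
        for i in range(n):
            crops.append(tiny_crop(label, f"c{label}-{i}", size))
    return crops


@pytest.fixture
def zero_scores():
    return FieldScores(0, 0, 0, 0, 0)


def record(x, y, tree_id="t0", scores=None, dead=False):
    return TreeRecord(tree_id, x, y, scores or FieldScores(0, 0, 0, 0, 0),
                      dead)
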