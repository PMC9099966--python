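"""Kennard-Stone calibration/validation partitioning.

Deterministic max-min selection on Euclidean distances: the pair of
samples at maximum distance seeds the training set; each further
training sample is the candidate whose minimum distance to the already
selected set is largest.  Ties break to the lowest sample index, so the
split is bit-reproducible.  The remainder forms the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .blocks import SpectraBlock

__all__ = ["SplitIndex", "kennard_stone"]


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint ordered train/test id sets covering all samples."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)

    def save(self, path) -> None:
        df = pd.DataFrame(
            {
                "sample_id": list(self.train_ids) + list(self.test_ids),
                "partition": ["train"] * self.n_train + ["test"] * self.n_test,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "SplitIndex":
        df = pd.read_csv(path, dtype=str)
        train = tuple(df.loc[df["partition"] == "train", "sample_id"])
        test = tuple(df.loc[df["partition"] == "test", "sample_id"])
        n = len(train) + len(test)
        return cls(train_ids=train, test_ids=test, fraction=len(train) / n)


def kennard_stone(block: SpectraBlock, fraction: float = 0.8) -> SplitIndex:
    """Partition a block's samples by the Kennard-Stone max-min rule.

    ``fraction`` is the target training proportion; the training size is
    ``floor(fraction * n)`` (so 196 samples at 0.8 give a 156/40 split).
    """
    n = block.n_samples
    if n < 2:
        raise ValueError("kennard_stone requires at least 2 samples")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction!r}")
    n_train = int(np.floor(fraction * n))
    if n_train < 2:
        raise ValueError(
            f"fraction {fraction} yields a training set of {n_train} < 2 samples"
        )

    dist = squareform(pdist(block.values, metric="euclidean"))
    # seed: the pair at global maximum distance; ties -> lowest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat))
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    selected = [i0, j0]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i0, j0]] = True

    # min distance of every candidate to the selected set, updated incrementally
    min_dist = np.minimum(dist[i0], dist[j0])
    while len(selected) < n_train:
        min_dist[in_set] = -np.inf
        nxt = int(np.argmax(min_dist))  # ties -> lowest index
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])

    test = [i for i in range(n) if not in_set[i]]
    return SplitIndex(
        train_ids=tuple(block.samples[i] for i in selected),
        test_ids=tuple(block.samples[i] for i in test),
        fraction=fraction,
    )
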