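"""Duplex sample-set partitioning.

The duplex algorithm selects a representative external test set directly in
the original (un-pre-treated) spectral data space: the pair of samples with
the largest Euclidean distance goes to the training set, the next most
distant pair among the remaining samples goes to the test set, the third
pair to training again, and so on until the test set holds the requested
number of samples; everything still unassigned then joins the training set.
Both sets therefore span the data space, unlike a random split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import SpectraSet, ValidationError


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive train/test partition (sorted original indices)."""

    train_indices: np.ndarray
    test_indices: np.ndarray


def duplex_split(x, n_test: int) -> SplitResult:
    """Deterministic duplex partition of ``x`` (matrix or :class:`SpectraSet`).

    Tie-breaks, which the pairwise construction leaves open, are fixed for
    determinism: among equally distant pairs the lexicographically smallest
    index pair wins; when a single test slot remains (odd ``n_test``), the
    member of the current most-distant pair with the larger minimum distance
    to the already selected test samples is taken, lower index on ties.
    """
    if isinstance(x, SpectraSet):
        x = x.absorbance
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 4:
        raise ValidationError("duplex needs at least 4 samples")
    if not 1 <= n_test <= n - 2:
        raise ValidationError(f"n_test={n_test} must lie in [1, {n - 2}]")

    d = squareform(pdist(x))
    # row-major argmax over the upper triangle == lexicographic tie-break
    iu = np.triu_indices(n, k=1)
    alive = np.ones(n, dtype=bool)
    train: list[int] = []
    test: list[int] = []
    to_train = True
    while len(test) < n_test:
        pair_alive = alive[iu[0]] & alive[iu[1]]
        if not pair_alive.any():
            raise ValidationError(
                "ran out of samples before the test set was filled"
            )
        dv = np.where(pair_alive, d[iu], -np.inf)
        k = int(np.argmax(dv))
        i, j = int(iu[0][k]), int(iu[1][k])
        if not to_train and n_test - len(test) == 1:
            if test:
                mi = d[i, test].min()
                mj = d[j, test].min()
            else:
                mi = mj = np.inf
            pick = i if mi >= mj else j
            test.append(pick)
            alive[pick] = False
        else:
            (train if to_train else test).extend((i, j))
            alive[i] = alive[j] = False
        to_train = not to_train
    train.extend(np.flatnonzero(alive).tolist())
    return SplitResult(
        np.array(sorted(train), dtype=int), np.array(sorted(test), dtype=int)
    )
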