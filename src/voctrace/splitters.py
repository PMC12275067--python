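"""Kennard-Stone sample-set partitioning.

The K-S algorithm builds a representative subset deterministically: it first
picks the two most distant samples (Euclidean distance in the supplied
feature space), then repeatedly adds the sample whose minimum distance to
the already-selected set is largest.  Splits at ratios such as 7:3, 7:2:1 or
2:1 apply the algorithm sequentially: the first subset is selected from all
samples, the next from the remainder, and the last subset is the remainder
itself.  Subset sizes follow largest-remainder rounding; ties in the
selection rule break toward the lowest index so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class SplitResult:
    """Disjoint ordered index subsets covering all samples."""

    subsets: list[list[int]]
    ratios: tuple[float, ...]
    metric: str = "euclidean"

    def __iter__(self):
        return iter(self.subsets)


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Ordered max-min Kennard-Stone selection of k of n rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")

    d = cdist(X, X)
    # farthest pair; ties -> lexicographically smallest (i, j)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    first = [min(i, j), max(i, j)] if i != j else [0, 1]
    selected = list(first)
    remaining = [r for r in range(n) if r not in selected]
    min_d = d[:, selected].min(axis=1)

    while len(selected) < k:
        cand = remaining[int(np.argmax(min_d[remaining]))]  # argmax: first max wins
        selected.append(cand)
        remaining.remove(cand)
        min_d = np.minimum(min_d, d[:, cand])
    return selected


def largest_remainder_sizes(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion n into len(ratios) integers proportional to the ratios."""
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    quota = np.array(ratios) / sum(ratios) * n
    sizes = np.floor(quota).astype(int)
    rem = quota - sizes
    for idx in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[idx] += 1
    return sizes.tolist()


def split(
    X: np.ndarray,
    ratios: tuple[float, ...],
    sizes: list[int] | None = None,
) -> SplitResult:
    """Sequential Kennard-Stone split at the given ratios.

    ``sizes`` overrides the largest-remainder subset sizes (they must still
    sum to n), for reproducing externally reported counts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if sizes is None:
        sizes = largest_remainder_sizes(n, ratios)
    if sum(sizes) != n:
        raise ValueError(f"sizes {sizes} do not sum to n={n}")
    if any(sz == 0 for sz in sizes):
        raise ValueError(f"a subset would be empty for n={n}, ratios={ratios}")

    pool = list(range(n))
    subsets: list[list[int]] = []
    for sz in sizes[:-1]:
        local = kennard_stone(X[pool], sz)
        chosen = [pool[i] for i in local]
        subsets.append(chosen)
        pool = [p for p in pool if p not in chosen]
    subsets.append(pool)
    return SplitResult(subsets=subsets, ratios=tuple(ratios))
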