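"""Canberra distances between ranked partial feature lists.

Feature-selection runs on resampled data yield ranked marker lists that
rarely agree exactly; the mean pairwise Canberra distance between the lists
quantifies how reproducible the selection is (lower = more stable) and is
the second axis, next to cross-validated error, used for model selection.

A partial list of length k over p features is completed to a full rank
vector by giving every unlisted feature the mean unoccupied rank
(k + 1 + p) / 2 — the per-element expectation over all uniform extensions
of the list to a full permutation.  The Canberra distance between rank
vectors a and b is sum_i |a_i - b_i| / (a_i + b_i); because the denominator
grows with rank, a swap near the top of a list costs more than the same
displacement near the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "StabilityValue",
    "canberra_on_ranks",
    "complete_ranks",
    "canberra_partial",
    "stability_indicator",
    "expected_null_distance",
    "write_ranked_list",
    "read_ranked_list",
]


@dataclass(frozen=True)
class RankedList:
    """Ordered partial list of feature identifiers over a fixed universe."""

    items: tuple
    universe: tuple

    def __init__(self, items: Sequence[str], universe: Sequence[str]):
        items = tuple(items)
        universe = tuple(universe)
        if len(set(items)) != len(items):
            raise ValueError("duplicate items in ranked list")
        if len(set(universe)) != len(universe):
            raise ValueError("duplicate features in universe")
        extra = set(items) - set(universe)
        if extra:
            raise ValueError(f"items not in universe: {sorted(extra)[:5]}")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "universe", universe)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def universe_size(self) -> int:
        return len(self.universe)


@dataclass(frozen=True)
class StabilityValue:
    mean_distance: float
    n_lists: int
    normalization: str = "raw"  # "raw" | "max_normalized"


def canberra_on_ranks(a: np.ndarray, b: np.ndarray) -> float:
    """Classical Canberra distance sum |a-b| / (a+b) between positive rank vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rank vectors differ in length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ranks must be positive")
    return float(np.sum(np.abs(a - b) / (a + b)))


def complete_ranks(L: RankedList) -> np.ndarray:
    """Full rank vector (aligned to the universe order) for a partial list.

    Listed items get ranks 1..k in list order; every unlisted feature gets
    the constant rank (k + 1 + p) / 2, the mean of the unoccupied positions
    k+1 .. p.
    """
    p = L.universe_size
    k = len(L)
    ranks = np.full(p, (k + 1 + p) / 2.0)
    index = {nm: i for i, nm in enumerate(L.universe)}
    for r, nm in enumerate(L.items, start=1):
        ranks[index[nm]] = r
    return ranks


def canberra_partial(L1: RankedList, L2: RankedList) -> float:
    """Canberra distance between two partial lists on a common universe."""
    if L1.universe != L2.universe:
        raise ValueError("ranked lists have different universes")
    return canberra_on_ranks(complete_ranks(L1), complete_ranks(L2))


def stability_indicator(lists: Iterable[RankedList], normalization: str = "raw") -> StabilityValue:
    """Mean pairwise Canberra distance among a set of ranked lists.

    normalization="max_normalized" divides by the expected distance between
    two uniformly random full permutations of the universe, giving a
    scale-free score for plotting; model selection uses the raw value.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("stability requires at least two lists")
    universe = lists[0].universe
    for L in lists[1:]:
        if L.universe != universe:
            raise ValueError("ranked lists have different universes")
    ranks = [complete_ranks(L) for L in lists]
    d = [canberra_on_ranks(ranks[i], ranks[j]) for i, j in combinations(range(len(lists)), 2)]
    mean = float(np.mean(d))
    if normalization == "max_normalized":
        mean /= expected_null_distance(len(universe))
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return StabilityValue(mean_distance=mean, n_lists=len(lists), normalization=normalization)


def expected_null_distance(p: int, n_draws: int = 200, seed: int = 20100) -> float:
    """Monte-Carlo expected Canberra distance between random full permutations."""
    if p < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    base = np.arange(1, p + 1, dtype=float)
    vals = [
        canberra_on_ranks(rng.permutation(base), rng.permutation(base))
        for _ in range(n_draws)
    ]
    return float(np.mean(vals))


def write_ranked_list(L: RankedList, weights: dict, path) -> None:
    """Serialize a ranked list as TSV: rank, feature, weight."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(L) + 1),
            "feature": list(L.items),
            "weight": [weights.get(nm, 0.0) for nm in L.items],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ranked_list(path, universe: Sequence[str]) -> RankedList:
    df = pd.read_csv(path, sep="\t")
    return RankedList(items=df["feature"].tolist(), universe=universe)
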