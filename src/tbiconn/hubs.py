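"""Hub identification by group-level betweenness rank.

For each subject group, per-node betweenness centralities are averaged across
the group's subjects, nodes are ranked 1..n (n = highest betweenness, ties
broken deterministically by node index), and the top 10% of ranks (9 of 90
nodes on a 90-region parcellation) are classified as hubs. Hub sets are then
compared across groups: shared hubs, group-specific hubs, and the union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

DEFAULT_HUB_FRACTION = 0.10


def group_mean_betweenness(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of per-subject betweenness vectors (per node)."""
    if len(vectors) == 0:
        raise ValueError("cannot average betweenness over an empty group")
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("betweenness vectors must share a common parcellation length")
    return arr.mean(axis=0)


def rank_nodes(values: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n; the largest value gets rank n.

    Ties are broken by node index (lower index -> lower rank), making the
    ranking fully deterministic.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = values.size
    order = np.lexsort((np.arange(n), values))  # ascending value, then index
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def identify_hubs(ranks: np.ndarray, fraction: float = DEFAULT_HUB_FRACTION) -> set[int]:
    """Node indices in the top ``fraction`` of ranks (floor(fraction * n) nodes)."""
    ranks = np.asarray(ranks)
    n = ranks.size
    if not 0 < fraction < 1:
        raise ValueError("hub fraction must be in (0, 1)")
    n_hubs = math.floor(fraction * n)
    if n_hubs == 0:
        raise ValueError(f"fraction {fraction} selects zero hubs for n={n}")
    return set(np.flatnonzero(ranks > n - n_hubs).tolist())


@dataclass
class HubRanking:
    """Per-group betweenness ranking and derived hub set."""

    group: str
    mean_betweenness: np.ndarray
    rank: np.ndarray
    hub_set: set[int]

    @classmethod
    def from_group(
        cls,
        group: str,
        betweenness_vectors: Sequence[np.ndarray],
        fraction: float = DEFAULT_HUB_FRACTION,
    ) -> "HubRanking":
        mean_bc = group_mean_betweenness(betweenness_vectors)
        ranks = rank_nodes(mean_bc)
        return cls(group=group, mean_betweenness=mean_bc, rank=ranks,
                   hub_set=identify_hubs(ranks, fraction=fraction))


@dataclass
class HubOverlap:
    """Comparison of hub sets across groups."""

    shared: set[int]
    unique: dict[str, set[int]]
    union: set[int]


def hub_overlap(hub_sets: Mapping[str, set[int]]) -> HubOverlap:
    """Intersect and difference hub sets across >= 2 groups.

    ``unique[g]`` holds nodes that are hubs in group g and in no other group.
    """
    if len(hub_sets) < 2:
        raise ValueError("hub overlap requires at least two groups")
    sets = {g: set(s) for g, s in hub_sets.items()}
    shared = set.intersection(*sets.values())
    union = set.union(*sets.values())
    unique = {
        g: s - set.union(*(o for h, o in sets.items() if h != g))
        for g, s in sets.items()
    }
    return HubOverlap(shared=shared, unique=unique, union=union)
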